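"""Full-analysis orchestration from a single config.

Stage order mirrors the analysis chain: complete the target model from a
template, define the protein-DNA interface, build seeded interaction
networks, score conservation/uniqueness from the alignments, classify the
phenotype table and integrate everything into one cross-tabulation. A stage
whose input is absent is skipped and recorded. Outputs are written
atomically (temp file + rename) and carry a provenance block (config echo,
package version, input checksums, seed) sufficient to reproduce the run;
no timestamps, so identical configs give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .conservation import calls_to_frame, parse_alignment, uniqueness_scan, variable_positions
from .contacts import ContactCutoffs, base_contacts, interface_residues
from .network import build_network
from .phenotype import (
    DEFAULT_POU_SPAN,
    classify_defective,
    integrate,
    read_phenotype_tsv,
    write_phenotype_tsv,
)
from .structure import missing_sidechain_residues, parse_pdb, write_pdb
from .superpose import complete_model

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_CONFIG_FIELDS = {
    "schema_version", "target_structure", "template_structure", "ortholog_msa",
    "paralog_msa", "phenotype_table", "interface_cutoff", "hbond_cutoff",
    "salt_bridge_cutoff", "nonpolar_cutoff", "defect_threshold", "alpha",
    "min_paralog_subs", "pou_span", "network_seeds", "output_dir", "seed",
}


@dataclass
class RunConfig:
    output_dir: str
    target_structure: str | None = None
    template_structure: str | None = None
    ortholog_msa: str | None = None
    paralog_msa: str | None = None
    phenotype_table: str | None = None
    interface_cutoff: float = 3.6
    hbond_cutoff: float = 3.5
    salt_bridge_cutoff: float = 4.0
    nonpolar_cutoff: float = 4.5
    defect_threshold: float = 0.5
    alpha: float = 0.05
    min_paralog_subs: int | None = None
    pou_span: tuple[int, int] = DEFAULT_POU_SPAN
    network_seeds: tuple[int, ...] = ()  # reference positions to seed networks at
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        for name in ("interface_cutoff", "hbond_cutoff", "salt_bridge_cutoff", "nonpolar_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.interface_cutoff > self.nonpolar_cutoff:
            raise ValueError("interface cutoff must not exceed the nonpolar cutoff")
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {self.schema_version}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        unknown = set(data) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pou_span" in data:
            data["pou_span"] = tuple(data["pou_span"])
        if "network_seeds" in data:
            data["network_seeds"] = tuple(data["network_seeds"])
        return cls(**data)

    @property
    def cutoffs(self) -> ContactCutoffs:
        return ContactCutoffs(
            interface=self.interface_cutoff,
            hydrogen_bond=self.hbond_cutoff,
            salt_bridge=self.salt_bridge_cutoff,
            nonpolar=self.nonpolar_cutoff,
        )


@dataclass
class RunReport:
    outputs: dict[str, str] = field(default_factory=dict)  # artifact name -> path
    skipped: dict[str, str] = field(default_factory=dict)  # stage -> reason
    failures: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_atomic(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute every stage whose inputs are present; abort before any output
    on validation failure, record per-stage failures otherwise."""
    from . import __version__

    report = RunReport()
    inputs = {
        name: getattr(config, name)
        for name in (
            "target_structure", "template_structure", "ortholog_msa",
            "paralog_msa", "phenotype_table",
        )
        if getattr(config, name)
    }
    for name, path in inputs.items():
        if not Path(path).is_file():
            raise FileNotFoundError(f"{name} input does not exist: {path}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.provenance = {
        "package_version": __version__,
        "schema_version": config.schema_version,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "input_sha256": {name: _sha256(path) for name, path in inputs.items()},
        "seed": config.seed,
    }

    def emit(name: str, filename: str, text: str):
        path = outdir / filename
        _write_atomic(path, text)
        report.outputs[name] = str(path)

    model = interface_report = None
    if config.target_structure:
        model = parse_pdb(Path(config.target_structure).read_text())
        log.info("target model: %d atoms", model.n_atoms())
        if config.template_structure:
            template = parse_pdb(Path(config.template_structure).read_text())
            missing = missing_sidechain_residues(model)
            log.info("completing %d residues with missing side chains", len(missing))
            try:
                model, graft_report = complete_model(model, template, missing)
                lines = ["residue\tstatus\tlocal_rmsd\tdetail"]
                for e in graft_report:
                    lines.append(
                        f"{e['residue']}\t{e['status']}\t{e['local_rmsd']:.4f}\t{e['detail']}"
                    )
                emit("grafting_report", "grafting_report.tsv", "\n".join(lines) + "\n")
                emit("completed_model", "completed_model.pdb", write_pdb(model))
            except Exception as exc:  # stage failure: record, continue
                report.failures["completion"] = str(exc)
        else:
            report.skipped["completion"] = "no template structure given"
        try:
            interface_report = interface_residues(model, cutoffs=config.cutoffs)
            emit("interface_tsv", "interface.tsv", interface_report.to_tsv())
            emit("interface_json", "interface.json", interface_report.to_json())
        except Exception as exc:
            report.failures["interface"] = str(exc)
        if config.network_seeds and interface_report is not None:
            try:
                seeds = []
                for pos in config.network_seeds:
                    for cid in model.protein_chains():
                        try:
                            seeds.append(model.find_residue(cid, pos))
                            break
                        except KeyError:
                            continue
                graph = build_network(model, seeds, depth=1, cutoffs=config.cutoffs)
                emit("network_tsv", "network_edges.tsv", graph.to_tsv())
                emit("network_graphml", "network.graphml", graph.to_graphml())
            except Exception as exc:
                report.failures["network"] = str(exc)
        elif not config.network_seeds:
            report.skipped["network"] = "no network seeds configured"
    else:
        report.skipped["structure"] = "no target structure given"

    unique_positions: set[int] = set()
    if config.ortholog_msa and config.paralog_msa:
        try:
            ortho = parse_alignment(Path(config.ortholog_msa).read_text())
            para = parse_alignment(Path(config.paralog_msa).read_text())
            calls = uniqueness_scan(ortho, para, min_paralog_subs=config.min_paralog_subs)
            unique_positions = {c.ref_position for c in calls if c.unique}
            emit("uniqueness_tsv", "uniqueness.tsv",
                 calls_to_frame(calls).to_csv(sep="\t", index=False))
            var = variable_positions(ortho)
            emit("variable_positions", "variable_positions.tsv",
                 "ref_position\n" + "".join(f"{p}\n" for p in var))
        except Exception as exc:
            report.failures["conservation"] = str(exc)
    else:
        report.skipped["conservation"] = "ortholog and/or paralog alignment missing"

    if config.phenotype_table:
        try:
            records = read_phenotype_tsv(Path(config.phenotype_table).read_text())
            records = classify_defective(
                records, threshold=config.defect_threshold, alpha=config.alpha
            )
            emit("phenotypes_tsv", "phenotypes.tsv", write_phenotype_tsv(records))
            if interface_report is not None:
                table = integrate(
                    records,
                    interface_positions=set(interface_report.positions()),
                    base_positions={r.ref_position for r in base_contacts(interface_report)},
                    backbone_positions={
                        r.ref_position for r in interface_report.residues if r.touches_backbone
                    },
                    unique_positions=unique_positions,
                    pou_span=config.pou_span,
                )
                emit("integration_tsv", "integration.tsv", table.to_tsv())
                emit("integration_json", "integration.json", table.to_json())
            else:
                report.skipped["integration"] = "no interface report available"
        except Exception as exc:
            report.failures["phenotype"] = str(exc)
    else:
        report.skipped["phenotype"] = "no phenotype table given"

    emit(
        "summary",
        "summary.json",
        json.dumps(
            {
                "provenance": report.provenance,
                "outputs": sorted(report.outputs),
                "skipped": report.skipped,
                "failures": report.failures,
            },
            indent=2,
            sort_keys=True,
        ),
    )
    return report
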