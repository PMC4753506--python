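"""Hierarchical container for one protein-DNA complex and PDB input/output.

The model keeps author (PDB) numbering; an optional :class:`NumberingMap`
translates author residue numbers to reference protein positions. The
default is the identity map, appropriate when a deposited structure is
already numbered by the reference protein's positions.

Parsing is delegated to gemmi; only the first MODEL block is kept, altloc
groups are resolved to the highest-occupancy conformer (ties broken by
altloc letter), and waters plus non-polymer heteroatoms are dropped.
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import chemdata
from .chemdata import AMINO_ACIDS, NUCLEOTIDES, SIDECHAIN_ATOMS

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "StructureModel",
    "NumberingMap",
    "parse_pdb",
    "write_pdb",
    "classify_chains",
    "missing_sidechain_residues",
]


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    coords: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1] for {self.name!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True, order=True)
class ResidueKey:
    chain_id: str
    resnum: int
    icode: str = ""
    resname: str = ""

    def __str__(self) -> str:
        one = chemdata.THREE_TO_ONE.get(self.resname, self.resname)
        return f"{one}{self.resnum}{self.icode}"


class StructureModel:
    """Ordered chains of residues, each residue a list of heavy atoms."""

    def __init__(self):
        # chain_id -> {ResidueKey: [AtomRecord, ...]} (insertion ordered)
        self.chains: dict[str, dict[ResidueKey, list[AtomRecord]]] = {}
        self.metadata: dict = {"grafted_residues": set()}

    # -- construction --------------------------------------------------------

    def add_atom(self, key: ResidueKey, atom: AtomRecord) -> None:
        residues = self.chains.setdefault(key.chain_id, {})
        residues.setdefault(key, []).append(atom)

    def copy(self) -> "StructureModel":
        new = StructureModel()
        for cid, residues in self.chains.items():
            new.chains[cid] = {k: list(v) for k, v in residues.items()}
        new.metadata = _copy.deepcopy(self.metadata)
        return new

    # -- access ---------------------------------------------------------------

    def residues(self, chain_id: str | None = None):
        if chain_id is not None:
            yield from self.chains[chain_id]
        else:
            for residues in self.chains.values():
                yield from residues

    def atoms(self, key: ResidueKey) -> list[AtomRecord]:
        return self.chains[key.chain_id][key]

    def atom(self, key: ResidueKey, name: str) -> AtomRecord | None:
        for a in self.chains[key.chain_id][key]:
            if a.name == name:
                return a
        return None

    def coords(self, key: ResidueKey) -> np.ndarray:
        return np.array([a.coords for a in self.atoms(key)], dtype=float)

    def find_residue(self, chain_id: str, resnum: int, icode: str = "") -> ResidueKey:
        for key in self.chains[chain_id]:
            if key.resnum == resnum and key.icode == icode:
                return key
        raise KeyError(f"no residue {resnum}{icode} in chain {chain_id}")

    @property
    def chain_types(self) -> dict[str, str]:
        return classify_chains(self)

    def protein_chains(self) -> list[str]:
        return [c for c, t in self.chain_types.items() if t == "protein"]

    def dna_chains(self) -> list[str]:
        return [c for c, t in self.chain_types.items() if t == "dna"]

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a protein chain (X for unknown names)."""
        return "".join(
            chemdata.THREE_TO_ONE.get(k.resname, "X") for k in self.chains[chain_id]
        )

    def n_atoms(self) -> int:
        return sum(len(v) for res in self.chains.values() for v in res.values())


@dataclass
class NumberingMap:
    """Per-chain author-residue-number -> reference-position map.

    An empty per-chain table means identity. The mapping must be injective
    within each chain.
    """

    tables: dict[str, dict[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        for cid, table in self.tables.items():
            if len(set(table.values())) != len(table):
                raise ValueError(f"numbering map for chain {cid!r} is not injective")

    def ref_position(self, chain_id: str, resnum: int) -> int:
        table = self.tables.get(chain_id)
        if not table:
            return resnum
        return table.get(resnum, resnum)


# -----------------------------------------------------------------------------


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _validate_coordinate_fields(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldstr = line[lo:hi].strip()
            try:
                float(fieldstr)
            except ValueError:
                raise ValueError(
                    f"malformed {what} coordinate field {fieldstr!r} on line {lineno}: {line!r}"
                ) from None


def parse_pdb(text: str, keep_het: bool = False) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the first MODEL is read. Alternate locations are resolved to the
    highest-occupancy conformer (tie -> lowest altloc letter). Waters and
    non-polymer HETATM records are excluded unless ``keep_het``.
    """
    if not text.strip():
        raise ValueError("empty PDB input")
    _validate_coordinate_fields(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ValueError("no ATOM/HETATM records found")
    model = StructureModel()
    gmodel = st[0]
    n_atoms = 0
    for chain in gmodel:
        for res in chain:
            resname = res.name.strip()
            if resname in _WATER_NAMES:
                continue
            known = resname in AMINO_ACIDS or resname in NUCLEOTIDES
            if res.het_flag == "H" and not known and not keep_het:
                continue
            key = ResidueKey(
                chain_id=chain.name,
                resnum=res.seqid.num,
                icode=res.seqid.icode.strip(),
                resname=resname,
            )
            # resolve altlocs: group by atom name, keep best conformer
            by_name: dict[str, list] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            for name, group in by_name.items():
                best = min(group, key=lambda a: (-a.occ, a.altloc or " "))
                altloc = best.altloc if best.altloc and best.altloc != "\0" else ""
                model.add_atom(
                    key,
                    AtomRecord(
                        name=name,
                        element=best.element.name or chemdata.element_of(name),
                        coords=(best.pos.x, best.pos.y, best.pos.z),
                        altloc=altloc.strip(),
                        occupancy=min(max(best.occ, 0.0), 1.0),
                    ),
                )
                n_atoms += 1
    if n_atoms == 0:
        raise ValueError("no polymer atoms retained after filtering")
    return model


def write_pdb(model: StructureModel) -> str:
    """Serialise a model to PDB format (deterministic byte-stable output)."""
    lines: list[str] = []
    serial = 0
    for chain_id, residues in model.chains.items():
        last_key = None
        for key, atoms in residues.items():
            for atom in atoms:
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {name}{atom.altloc or ' ':1.1s}"
                    f"{key.resname:>3s} {chain_id:1.1s}{key.resnum:4d}"
                    f"{key.icode or ' ':1.1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
            last_key = key
        if last_key is not None:
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last_key.resname:>3s} "
                f"{chain_id:1.1s}{last_key.resnum:4d}{last_key.icode or ' ':1.1s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def classify_chains(model: StructureModel) -> dict[str, str]:
    """Type every chain as protein / dna / other.

    A chain mixing amino acids and nucleotides violates the one-polymer-type
    invariant and raises, listing the offending residues.
    """
    if not model.chains:
        raise ValueError("empty model")
    types: dict[str, str] = {}
    for cid, residues in model.chains.items():
        aa = [k for k in residues if k.resname in AMINO_ACIDS]
        nt = [k for k in residues if k.resname in NUCLEOTIDES]
        if aa and nt:
            minority = nt if len(aa) >= len(nt) else aa
            listing = ", ".join(f"{k.resname} {k.resnum}" for k in minority)
            raise ValueError(
                f"chain {cid!r} mixes amino acids and nucleotides: {listing}"
            )
        if aa and len(aa) == len(residues):
            types[cid] = "protein"
        elif nt and len(nt) == len(residues):
            types[cid] = "dna"
        else:
            types[cid] = "other"
    return types


def missing_sidechain_residues(model: StructureModel) -> list[ResidueKey]:
    """Protein residues lacking any canonical heavy side-chain atom.

    Glycine is never reported (no side chain beyond CA); residues with an
    unrecognised name are skipped with a warning.
    """
    out: list[ResidueKey] = []
    chain_types = model.chain_types
    for cid, residues in model.chains.items():
        if chain_types[cid] == "dna":
            continue
        if not any(k.resname in AMINO_ACIDS for k in residues):
            continue
        for key in residues:
            expected = SIDECHAIN_ATOMS.get(key.resname)
            if expected is None:
                warnings.warn(
                    f"unknown residue name {key.resname!r} at {cid}/{key.resnum}; skipped"
                )
                continue
            if not expected:  # GLY
                continue
            present = {a.name for a in model.atoms(key)}
            if any(name not in present for name in expected):
                out.append(key)
    return out
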