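"""Normalisation and classification of alanine-scan readouts.

Three wet-lab readouts are supported:

* reprogramming efficiency — GFP+ iPSC colony counts per replicate,
  expressed as a fraction of the wild-type mean;
* transactivation — dual-luciferase reporters, firefly normalised by
  co-transfected renilla and expressed as fold over a mock control;
* protein stability — western-blot band intensities over a cycloheximide
  chase, Oct4 normalised by a GFP co-expression control and rescaled so the
  t = 0 level is 1; the half-life comes from a log-linear decay fit.

A mutant is classified *defective* when its colony fraction falls below a
threshold (default 0.5x WT) **and** the replicate comparison against WT is
significant under an exact one-sided permutation test on replicate values
(small-n count data, no normality assumption); *reduced* when significant
but above the threshold; otherwise *normal*.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, replace
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeRecord",
    "ReporterRecord",
    "StabilityRecord",
    "IntegrationTable",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "normalize_colonies",
    "permutation_pvalue",
    "classify_defective",
    "normalize_reporter",
    "normalize_band_intensity",
    "estimate_half_life",
    "integrate",
]

DEFAULT_POU_SPAN = (131, 289)  # mOct4 numbering; config-overridable


@dataclass
class PhenotypeRecord:
    mutant: str
    positions: tuple[int, ...]
    counts: tuple[int, ...]
    fraction_of_wt: float | None = None
    defect_class: str | None = None
    p_value: float | None = None
    threshold_only: bool = False  # set when < 2 replicates forced a threshold-only call

    def __post_init__(self):
        if any(c < 0 for c in self.counts):
            raise ValueError(f"negative colony count in {self.mutant!r}")
        if self.fraction_of_wt is not None and self.fraction_of_wt < 0:
            raise ValueError("fraction_of_wt must be >= 0")

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.counts))

    @property
    def multi_site(self) -> bool:
        return len(self.positions) > 1


@dataclass
class ReporterRecord:
    construct: str
    reporter: str  # "6xCR4" or "5xW"
    firefly: tuple[float, ...]
    renilla: tuple[float, ...]
    relative_activity: float | None = None

    def __post_init__(self):
        if any(r <= 0 for r in self.renilla):
            raise ValueError(f"non-positive renilla reading in {self.construct!r}")


@dataclass
class StabilityRecord:
    construct: str
    timepoints_h: tuple[float, ...]
    oct4_intensity: tuple[float, ...]
    gfp_intensity: tuple[float, ...]
    relative_level: tuple[float, ...] | None = None
    half_life_h: float | None = None


# --- colony counts -----------------------------------------------------------


def read_phenotype_tsv(text: str) -> list[PhenotypeRecord]:
    """Read a mutant table. Columns: mutant, positions (comma-sep), counts (comma-sep)."""
    df = pd.read_csv(StringIO(text), sep="\t", dtype=str)
    required = {"mutant", "positions", "counts"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        raw_pos = "" if pd.isna(row["positions"]) else str(row["positions"])
        positions = tuple(int(p) for p in raw_pos.split(",") if p.strip())
        counts = tuple(int(c) for c in str(row["counts"]).split(",") if c.strip())
        records.append(PhenotypeRecord(mutant=row["mutant"], positions=positions, counts=counts))
    return records


def write_phenotype_tsv(records: list[PhenotypeRecord]) -> str:
    rows = []
    for r in records:
        row = {
            "mutant": r.mutant,
            "positions": ",".join(map(str, r.positions)),
            "counts": ",".join(map(str, r.counts)),
        }
        if r.fraction_of_wt is not None:
            row["fraction_of_wt"] = f"{r.fraction_of_wt:.6g}"
        if r.defect_class is not None:
            row["defect_class"] = r.defect_class
        rows.append(row)
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


def _wt_record(records: list[PhenotypeRecord], wt_label: str) -> PhenotypeRecord:
    for r in records:
        if r.mutant == wt_label:
            return r
    raise ValueError(f"no wild-type record labelled {wt_label!r}")


def normalize_colonies(
    records: list[PhenotypeRecord], wt_label: str = "WT"
) -> list[PhenotypeRecord]:
    """Express each mutant's replicate-mean colony count as a fraction of WT."""
    wt = _wt_record(records, wt_label)
    if wt.mean_count <= 0:
        raise ValueError("wild-type mean colony count is zero; cannot normalize")
    return [replace(r, fraction_of_wt=r.mean_count / wt.mean_count) for r in records]


def permutation_pvalue(
    x: tuple[float, ...] | list[float],
    y: tuple[float, ...] | list[float],
    alternative: str = "less",
) -> float:
    """Exact permutation p-value for mean(x) - mean(y) by full enumeration.

    Enumerates every reassignment of the pooled replicates to the two groups
    (feasible at replicate-scale n). ``alternative='less'`` tests whether x
    is stochastically smaller than y.
    """
    x, y = list(map(float, x)), list(map(float, y))
    pooled = x + y
    nx = len(x)
    observed = np.mean(x) - np.mean(y)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        in_x = set(combo)
        gx = [pooled[i] for i in in_x]
        gy = [pooled[i] for i in range(len(pooled)) if i not in in_x]
        stat = np.mean(gx) - np.mean(gy)
        total += 1
        if alternative == "less":
            count += stat <= observed + 1e-12
        elif alternative == "greater":
            count += stat >= observed - 1e-12
        else:  # two-sided
            count += abs(stat) >= abs(observed) - 1e-12
    return count / total


def classify_defective(
    records: list[PhenotypeRecord],
    wt_label: str = "WT",
    threshold: float = 0.5,
    alpha: float = 0.05,
) -> list[PhenotypeRecord]:
    """Call each mutant defective / reduced / normal against the WT replicates.

    defective: fraction_of_wt < threshold and significantly fewer colonies;
    reduced:   significantly fewer but fraction >= threshold;
    normal:    otherwise. With < 2 replicates on either side the significance
    requirement is dropped (threshold only) and the record flagged.
    """
    records = normalize_colonies(records, wt_label)
    wt = _wt_record(records, wt_label)
    out = []
    for r in records:
        if r.mutant == wt_label:
            out.append(replace(r, defect_class="normal", p_value=1.0))
            continue
        if len(r.counts) < 2 or len(wt.counts) < 2:
            cls = "defective" if r.fraction_of_wt < threshold else "normal"
            out.append(replace(r, defect_class=cls, threshold_only=True))
            continue
        p = permutation_pvalue(r.counts, wt.counts, alternative="less")
        significant = p <= alpha
        if significant and r.fraction_of_wt < threshold:
            cls = "defective"
        elif significant:
            cls = "reduced"
        else:
            cls = "normal"
        out.append(replace(r, defect_class=cls, p_value=p))
    return out


# --- reporters and stability --------------------------------------------------


def normalize_reporter(record: ReporterRecord, mock: ReporterRecord) -> ReporterRecord:
    """Firefly/renilla of the construct as fold over the mock control."""
    mock_ratio = float(np.mean(np.asarray(mock.firefly) / np.asarray(mock.renilla)))
    if mock_ratio <= 0:
        raise ValueError("mock firefly/renilla ratio is non-positive")
    ratio = float(np.mean(np.asarray(record.firefly) / np.asarray(record.renilla)))
    return replace(record, relative_activity=ratio / mock_ratio)


def normalize_band_intensity(record: StabilityRecord) -> StabilityRecord:
    """(Oct4 / GFP) per timepoint, rescaled so the t = 0 level equals 1."""
    gfp = np.asarray(record.gfp_intensity, float)
    if np.any(gfp <= 0):
        raise ValueError(f"non-positive GFP band intensity in {record.construct!r}")
    ratio = np.asarray(record.oct4_intensity, float) / gfp
    t0 = ratio[list(record.timepoints_h).index(min(record.timepoints_h))]
    if t0 <= 0:
        raise ValueError("zero Oct4 signal at the first timepoint")
    return replace(record, relative_level=tuple(float(v) for v in ratio / t0))


def estimate_half_life(
    timepoints_h: tuple[float, ...], relative_level: tuple[float, ...]
) -> float | None:
    """Half-life from a least-squares fit of log(level) vs time.

    Returns None (undefined) when the fitted decay rate is non-negative,
    i.e. the series does not decay.
    """
    t = np.asarray(timepoints_h, float)
    lv = np.asarray(relative_level, float)
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints")
    if np.any(lv <= 0):
        raise ValueError("relative levels must be positive for a log-linear fit")
    slope, _ = np.polyfit(t, np.log(lv), 1)
    if slope >= 0:
        return None
    return float(math.log(2) / (-slope))


# --- integration ----------------------------------------------------------------


@dataclass
class IntegrationTable:
    table: pd.DataFrame  # one row per mutated position
    counts_2x2: np.ndarray  # defective x interface
    fisher_p: float
    odds_ratio: float

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)

    def summary(self) -> dict:
        (a, b), (c, d) = self.counts_2x2
        return {
            "defective_interface": int(a),
            "defective_noninterface": int(b),
            "nondefective_interface": int(c),
            "nondefective_noninterface": int(d),
            "fisher_exact_p": self.fisher_p,
            "odds_ratio": self.odds_ratio,
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


def integrate(
    phenotypes: list[PhenotypeRecord],
    interface_positions: set[int] | None = None,
    base_positions: set[int] | None = None,
    backbone_positions: set[int] | None = None,
    unique_positions: set[int] | None = None,
    pou_span: tuple[int, int] = DEFAULT_POU_SPAN,
) -> IntegrationTable:
    """Join defect calls with structural and uniqueness annotations.

    One row per mutated position (multi-site mutants contribute their class
    to every mutated position, flagged as shared evidence); a position
    claimed by two different mutants is an error. The 2x2 defective-vs-
    interface table is tested with a two-sided exact (Fisher) test.
    """
    interface_positions = interface_positions or set()
    base_positions = base_positions or set()
    backbone_positions = backbone_positions or set()
    unique_positions = unique_positions or set()
    seen: dict[int, str] = {}
    collisions = []
    rows = []
    for rec in phenotypes:
        if rec.defect_class is None:
            raise ValueError(f"mutant {rec.mutant!r} not classified; run classify_defective first")
        if not rec.positions:
            continue
        for pos in rec.positions:
            if pos in seen and seen[pos] != rec.mutant:
                collisions.append((pos, seen[pos], rec.mutant))
                continue
            seen[pos] = rec.mutant
            rows.append(
                {
                    "position": pos,
                    "mutant": rec.mutant,
                    "defect_class": rec.defect_class,
                    "fraction_of_wt": rec.fraction_of_wt,
                    "shared_evidence": rec.multi_site,
                    "in_pou": pou_span[0] <= pos <= pou_span[1],
                    "interface": pos in interface_positions,
                    "touches_base": pos in base_positions,
                    "touches_backbone": pos in backbone_positions,
                    "unique": pos in unique_positions,
                }
            )
    if collisions:
        listing = "; ".join(f"position {p}: {m1!r} vs {m2!r}" for p, m1, m2 in collisions)
        raise ValueError(f"position collisions between mutants: {listing}")
    df = pd.DataFrame(
        rows,
        columns=[
            "position", "mutant", "defect_class", "fraction_of_wt", "shared_evidence",
            "in_pou", "interface", "touches_base", "touches_backbone", "unique",
        ],
    ).sort_values("position", kind="mergesort").reset_index(drop=True)
    if len(df):
        defective = df["defect_class"] == "defective"
        iface = df["interface"]
        a = int((defective & iface).sum())
        b = int((defective & ~iface).sum())
        c = int((~defective & iface).sum())
        d = int((~defective & ~iface).sum())
    else:
        a = b = c = d = 0
    counts = np.array([[a, b], [c, d]])
    if counts.sum() > 0:
        odds, p = stats.fisher_exact(counts, alternative="two-sided")
    else:
        odds, p = float("nan"), float("nan")
    return IntegrationTable(table=df, counts_2x2=counts, fisher_p=float(p), odds_ratio=float(odds))
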