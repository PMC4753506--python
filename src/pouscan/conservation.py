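"""Per-column conservation, paralog substitution counting and uniqueness calls.

Positions are reported in reference numbering: position p is the p-th
non-gap residue of the reference row. A "uniqueness position" is conserved
across every ortholog of the reference protein yet substituted in family
paralogs — by default in *all* non-reference paralogs, the strict reading
under which a residue is found in the reference protein and in no other
family member.

Gaps never count as substitutions; columns where the reference is gapped
carry no reference position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structure import ResidueKey, StructureModel

__all__ = [
    "AlignmentSet",
    "ColumnStats",
    "UniquenessCall",
    "parse_alignment",
    "write_alignment",
    "column_stats",
    "variable_positions",
    "substitution_profile",
    "uniqueness_scan",
    "map_alignment_to_structure",
]

log = logging.getLogger(__name__)

GAP = "-"


@dataclass
class AlignmentSet:
    ids: list[str]
    sequences: list[str]  # equal length, '-' gaps
    reference_id: str

    def __post_init__(self):
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in count")
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        length = len(self.sequences[0])
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != length:
                raise ValueError(
                    f"ragged alignment: sequence {sid!r} has length {len(seq)}, expected {length}"
                )
        if self.reference_id not in self.ids:
            raise ValueError(f"reference id {self.reference_id!r} not among records")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def reference_row(self) -> str:
        return self.sequences[self.ids.index(self.reference_id)]

    @property
    def reference_sequence(self) -> str:
        return self.reference_row.replace(GAP, "")

    def column_to_refpos(self) -> dict[int, int]:
        """0-based column index -> 1-based reference position (non-gap ref columns)."""
        mapping, pos = {}, 0
        for col, ch in enumerate(self.reference_row):
            if ch != GAP:
                pos += 1
                mapping[col] = pos
        return mapping

    def refpos_to_column(self) -> dict[int, int]:
        return {p: c for c, p in self.column_to_refpos().items()}

    def column(self, col: int) -> list[str]:
        return [s[col] for s in self.sequences]


def parse_alignment(text: str, reference_id: str | None = None) -> AlignmentSet:
    """Read an aligned-FASTA alignment; the first record is the default reference."""
    records = list(SeqIO.parse(StringIO(text), "fasta"))
    if len(records) < 2:
        raise ValueError("alignment needs at least 2 records")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return AlignmentSet(ids=ids, sequences=seqs, reference_id=reference_id or ids[0])


def write_alignment(aln: AlignmentSet) -> str:
    out = StringIO()
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, out, "fasta")
    return out.getvalue()


@dataclass
class ColumnStats:
    column: int  # 0-based alignment column
    ref_position: int  # 1-based reference position
    ref_residue: str
    n_match: int
    n_substituted: int
    n_gap: int
    substitutes: frozenset[str]

    @property
    def distinct_residues(self) -> frozenset[str]:
        return self.substitutes | {self.ref_residue}


def _stats_for_column(aln: AlignmentSet, col: int, refpos: int) -> ColumnStats:
    ref_res = aln.reference_row[col]
    chars = aln.column(col)
    n_gap = sum(c == GAP for c in chars)
    n_match = sum(c == ref_res for c in chars)
    subs = frozenset(c for c in chars if c not in (GAP, ref_res))
    return ColumnStats(
        column=col,
        ref_position=refpos,
        ref_residue=ref_res,
        n_match=n_match,
        n_substituted=len(chars) - n_match - n_gap,
        n_gap=n_gap,
        substitutes=subs,
    )


def column_stats(aln: AlignmentSet) -> list[ColumnStats]:
    """One ColumnStats per non-gap reference column, in reference order."""
    return [
        _stats_for_column(aln, col, pos)
        for col, pos in sorted(aln.column_to_refpos().items())
    ]


def variable_positions(
    aln: AlignmentSet,
    region: tuple[int, int] | None = None,
    min_substitutions: int = 1,
) -> list[int]:
    """Reference positions within ``region`` carrying >= 1 substitution."""
    ref_len = len(aln.reference_sequence)
    if region is None:
        region = (1, ref_len)
    lo, hi = region
    if lo > hi or lo < 1 or hi > ref_len:
        raise ValueError(f"empty or out-of-range region {region} for reference length {ref_len}")
    return [
        s.ref_position
        for s in column_stats(aln)
        if lo <= s.ref_position <= hi and s.n_substituted >= min_substitutions
    ]


def substitution_profile(aln: AlignmentSet, ref_position: int) -> ColumnStats:
    """Column statistics at one reference position."""
    col = aln.refpos_to_column().get(ref_position)
    if col is None:
        raise ValueError(f"reference position {ref_position} is unmapped (gap or out of range)")
    return _stats_for_column(aln, col, ref_position)


@dataclass
class UniquenessCall:
    ref_position: int
    ref_residue: str
    ortholog_conserved: bool
    paralog_substitution_count: int
    paralog_substitutes: frozenset[str]
    unique: bool


def uniqueness_scan(
    ortholog_aln: AlignmentSet,
    paralog_aln: AlignmentSet,
    region: tuple[int, int] | None = None,
    min_paralog_subs: int | None = None,
) -> list[UniquenessCall]:
    """Positions conserved across orthologs but substituted in paralogs.

    ``min_paralog_subs`` defaults to the number of non-reference paralogs —
    every other family member must differ for the position to be unique.
    """
    if ortholog_aln.reference_sequence != paralog_aln.reference_sequence:
        raise ValueError("ortholog and paralog alignments disagree on the reference sequence")
    if min_paralog_subs is None:
        min_paralog_subs = paralog_aln.n_sequences - 1
    ref_len = len(ortholog_aln.reference_sequence)
    lo, hi = region if region is not None else (1, ref_len)
    ortho = {s.ref_position: s for s in column_stats(ortholog_aln)}
    para = {s.ref_position: s for s in column_stats(paralog_aln)}
    calls = []
    for pos in range(lo, hi + 1):
        so, sp = ortho.get(pos), para.get(pos)
        if so is None or sp is None:
            continue
        conserved = so.n_substituted == 0 and so.n_gap == 0
        calls.append(
            UniquenessCall(
                ref_position=pos,
                ref_residue=so.ref_residue,
                ortholog_conserved=conserved,
                paralog_substitution_count=sp.n_substituted,
                paralog_substitutes=sp.substitutes,
                unique=conserved and sp.n_substituted >= min_paralog_subs,
            )
        )
    return calls


def calls_to_frame(calls: list[UniquenessCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ref_position": c.ref_position,
                "ref_residue": c.ref_residue,
                "ortholog_conserved": c.ortholog_conserved,
                "paralog_substitution_count": c.paralog_substitution_count,
                "paralog_substitutes": "".join(sorted(c.paralog_substitutes)),
                "unique": c.unique,
            }
            for c in calls
        ],
        columns=[
            "ref_position", "ref_residue", "ortholog_conserved",
            "paralog_substitution_count", "paralog_substitutes", "unique",
        ],
    )


def map_alignment_to_structure(
    aln: AlignmentSet,
    model: StructureModel,
    chain_id: str,
    min_identity: float = 0.95,
) -> dict[int, ResidueKey]:
    """Reference position -> structure residue, by ungapped sequence walk.

    The chain is assumed to cover a contiguous span of the reference; the
    best-matching offset is chosen and must reach ``min_identity`` over the
    covered span. Point mismatches are logged, not fatal.
    """
    chain_seq = model.sequence(chain_id)
    ref = aln.reference_sequence
    if not chain_seq or len(chain_seq) > len(ref):
        span = min(len(chain_seq), len(ref))
    else:
        span = len(chain_seq)
    best_offset, best_matches = 0, -1
    for offset in range(0, len(ref) - span + 1):
        matches = sum(a == b for a, b in zip(chain_seq[:span], ref[offset : offset + span]))
        if matches > best_matches:
            best_offset, best_matches = offset, matches
    identity = best_matches / span if span else 0.0
    if identity < min_identity:
        raise ValueError(
            f"chain {chain_id!r} matches reference at {identity:.1%} identity, "
            f"below the {min_identity:.0%} floor"
        )
    keys = list(model.chains[chain_id])[:span]
    mapping: dict[int, ResidueKey] = {}
    for i, key in enumerate(keys):
        pos = best_offset + i + 1
        mapping[pos] = key
        if chain_seq[i] != ref[best_offset + i]:
            log.info(
                "sequence mismatch at reference position %d: chain %s vs reference %s",
                pos, chain_seq[i], ref[best_offset + i],
            )
    return mapping
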