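"""Static chemical reference tables.

Heavy-atom only throughout: crystal structures of protein-DNA complexes
rarely resolve hydrogens, so every distance criterion in this package is a
heavy-atom criterion. The canonical atom sets follow the standard chemical
component dictionary definitions for the 20 proteinogenic amino acids and
the four 2'-deoxyribonucleotides.
"""

from __future__ import annotations

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Side-chain heavy atoms beyond the backbone (CB included).
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

AMINO_ACIDS = frozenset(SIDECHAIN_ATOMS)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def heavy_atom_set(resname: str) -> tuple[str, ...]:
    """Canonical heavy atoms of an amino acid (backbone + side chain)."""
    return BACKBONE_ATOMS + SIDECHAIN_ATOMS[resname]


# --- deoxyribonucleotides ---------------------------------------------------

PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "O5'", "O3'"})
SUGAR_ATOMS = frozenset({"C1'", "C2'", "C3'", "C4'", "C5'", "O4'"})

BASE_ATOMS: dict[str, tuple[str, ...]] = {
    "DA": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "DG": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "DC": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "DT": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"),
}

NUCLEOTIDES = frozenset(BASE_ATOMS)

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def nucleotide_atom_set(resname: str, five_prime: bool = False) -> tuple[str, ...]:
    """Heavy atoms of a deoxyribonucleotide; 5' termini lack the phosphate."""
    backbone = () if five_prime else ("P", "OP1", "OP2")
    sugar = ("O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'")
    return backbone + sugar + BASE_ATOMS[resname]


def dna_moiety(atom_name: str, resname: str) -> str:
    """Partition a nucleotide atom into phosphate / sugar / base.

    O3' and O5' are assigned to the phosphate because they are part of the
    phosphodiester linkage ("backbone" in reports = phosphate + sugar).
    """
    if resname not in NUCLEOTIDES:
        raise ValueError(f"not a deoxyribonucleotide: {resname!r}")
    if atom_name in PHOSPHATE_ATOMS:
        return "phosphate"
    if atom_name in SUGAR_ATOMS:
        return "sugar"
    if atom_name in BASE_ATOMS[resname]:
        return "base"
    raise ValueError(f"unknown atom {atom_name!r} for nucleotide {resname}")


# --- hydrogen-bond capability (heavy-atom level, no angles) -----------------

# Protein donors: backbone N plus side-chain N/O carrying at least one H.
_PROTEIN_DONORS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "LYS": frozenset({"NZ"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TRP": frozenset({"NE1"}),
    "TYR": frozenset({"OH"}),
}

# Protein acceptors: backbone O plus side-chain lone-pair carriers.
_PROTEIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASN": frozenset({"OD1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLN": frozenset({"OE1"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
}

_DNA_DONORS: dict[str, frozenset[str]] = {
    "DA": frozenset({"N6"}),
    "DC": frozenset({"N4"}),
    "DG": frozenset({"N1", "N2"}),
    "DT": frozenset({"N3"}),
}

_DNA_ACCEPTORS: dict[str, frozenset[str]] = {
    "DA": frozenset({"N1", "N3", "N7"}),
    "DC": frozenset({"O2", "N3"}),
    "DG": frozenset({"N3", "N7", "O6"}),
    "DT": frozenset({"O2", "O4"}),
}

# All phosphate/sugar oxygens accept.
_DNA_BACKBONE_ACCEPTORS = frozenset({"OP1", "OP2", "O5'", "O3'", "O4'"})


def is_donor(resname: str, atom_name: str) -> bool:
    if resname in AMINO_ACIDS:
        if atom_name == "N":
            return resname != "PRO"
        return atom_name in _PROTEIN_DONORS.get(resname, frozenset())
    if resname in NUCLEOTIDES:
        return atom_name in _DNA_DONORS[resname]
    return False


def is_acceptor(resname: str, atom_name: str) -> bool:
    if resname in AMINO_ACIDS:
        if atom_name == "O":
            return True
        return atom_name in _PROTEIN_ACCEPTORS.get(resname, frozenset())
    if resname in NUCLEOTIDES:
        return atom_name in _DNA_ACCEPTORS[resname] or atom_name in _DNA_BACKBONE_ACCEPTORS
    return False


# --- formal charges ---------------------------------------------------------

BASIC_ATOMS: dict[str, frozenset[str]] = {
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

ACIDIC_ATOMS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

# The protein side of a salt bridge to DNA: any charged-group atom.
CHARGED_ATOMS: dict[str, frozenset[str]] = {**BASIC_ATOMS, **ACIDIC_ATOMS}

PHOSPHATE_OXYGENS = frozenset({"OP1", "OP2", "O5'", "O3'"})


def element_of(atom_name: str) -> str:
    """Element symbol inferred from a PDB atom name (heavy atoms only)."""
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[0].upper()
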