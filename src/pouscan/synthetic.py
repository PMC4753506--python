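"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here without downloads:

* an idealised B-form DNA duplex (exact rise 3.38 A and twist 36 deg per
  step, canonical atom names for every phosphate/sugar/base moiety);
* toy protein-DNA complexes in which each planted residue is posed so that
  exactly one atom pair realises a requested (contact class, DNA moiety,
  distance), decoy residues stay beyond a clearance, and optional
  residue-residue chains plant intra-protein network edges;
* ortholog/paralog alignment pairs with planted variable positions,
  substitution maps and uniqueness positions;
* simulated alanine-scan colony-count tables with planted defect fractions.

All generators are pure functions of (spec, seed). Geometry is stylised:
atom names and canonical atom sets are exact, local residue geometry is a
deterministic template (contact atom at the tip, remaining atoms retreating
along the pose axis), not rotamer-accurate chemistry — chemical realism is
out of scope, planted-label recovery is the contract and is validated
in-process, with bounded retries over pose candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import chemdata
from .chemdata import (
    BASE_ATOMS,
    COMPLEMENT,
    SIDECHAIN_ATOMS,
    element_of,
    heavy_atom_set,
    is_acceptor,
    is_donor,
)
from .conservation import AlignmentSet
from .contacts import ContactCutoffs, DEFAULT_CUTOFFS, classify_contact, classify_pair
from .phenotype import PhenotypeRecord
from .structure import AtomRecord, ResidueKey, StructureModel

__all__ = [
    "ComplexSpec",
    "PlantedContact",
    "NetworkPlant",
    "MsaSpec",
    "PhenotypeSpec",
    "generate_ideal_bdna",
    "generate_toy_complex",
    "generate_family_msa",
    "generate_phenotype_table",
    "paper_like_complex",
    "paper_like_msas",
    "paper_like_phenotype_spec",
]

RISE = 3.38  # A per base step
TWIST = 36.0  # deg per base step


# --------------------------------------------------------------------------
# idealised B-DNA
# --------------------------------------------------------------------------

# Local nucleotide frame as (radius A, azimuth deg, z A); the per-step
# transform is a TWIST rotation plus a RISE translation. Values are stylised
# but keep phosphates outermost, the sugar ring mid-radius and bases inner.
_SUGAR_PHOSPHATE_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "P": (8.9, -5.0, -1.0),
    "OP1": (10.1, -8.0, -1.2),
    "OP2": (9.3, 2.0, -2.0),
    "O5'": (7.9, -10.0, -0.6),
    "C5'": (7.4, -14.0, -0.2),
    "C4'": (6.9, -6.0, 0.2),
    "O4'": (6.5, -16.0, 0.8),
    "C3'": (7.3, 4.0, 0.6),
    "O3'": (8.3, 12.0, 1.2),
    "C2'": (6.4, 6.0, 1.2),
    "C1'": (5.8, -6.0, 1.0),
}

_PURINE_BASE = {
    "N9": (4.9, -4.0, 1.00),
    "C8": (4.6, 8.0, 1.10),
    "N7": (3.7, 12.0, 1.15),
    "C5": (3.2, 2.0, 1.10),
    "C4": (4.0, -8.0, 1.05),
    "N3": (3.6, -18.0, 1.00),
    "C2": (2.6, -20.0, 1.00),
    "N1": (1.9, -10.0, 1.05),
    "C6": (2.2, 2.0, 1.10),
}

_PYRIMIDINE_BASE = {
    "N1": (4.9, -4.0, 1.00),
    "C2": (4.0, -14.0, 1.00),
    "O2": (4.3, -26.0, 0.95),
    "N3": (3.0, -10.0, 1.00),
    "C4": (2.6, 2.0, 1.05),
    "C5": (3.4, 12.0, 1.10),
    "C6": (4.4, 8.0, 1.10),
}

_BASE_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "DA": {**_PURINE_BASE, "N6": (1.4, 10.0, 1.15)},
    "DG": {**_PURINE_BASE, "O6": (1.4, 10.0, 1.15), "N2": (2.2, -32.0, 0.95)},
    "DC": {**_PYRIMIDINE_BASE, "N4": (1.6, 6.0, 1.10)},
    "DT": {**_PYRIMIDINE_BASE, "O4": (1.6, 6.0, 1.10), "C7": (2.9, 26.0, 1.15)},
}

# Azimuthal offset of the complementary strand; != 180 deg so the two
# backbone traces leave unequal (major/minor) grooves, as in B-DNA.
_STRAND_B_OFFSET = 154.0


def _cyl(r: float, phi_deg: float, z: float) -> tuple[float, float, float]:
    a = math.radians(phi_deg)
    return (r * math.cos(a), r * math.sin(a), z)


def _nucleotide_atoms(resname: str, five_prime: bool) -> list[str]:
    return list(chemdata.nucleotide_atom_set(resname, five_prime=five_prime))


def generate_ideal_bdna(sequence: str, rise: float = RISE, twist: float = TWIST) -> StructureModel:
    """Idealised antiparallel B-form duplex for a sequence over {A, C, G, T}.

    Chain A carries the given sequence 5'->3', chain B the reverse
    complement. 5'-terminal nucleotides lack the phosphate group.
    """
    sequence = sequence.upper()
    if len(sequence) < 4:
        raise ValueError("duplex sequence must be at least 4 bases")
    bad = sorted(set(sequence) - set("ACGT"))
    if bad:
        raise ValueError(f"invalid characters in DNA sequence: {bad}")
    n = len(sequence)
    model = StructureModel()

    def place(chain_id: str, resnum: int, resname: str, step: int, mirror: bool, five_prime: bool):
        key = ResidueKey(chain_id=chain_id, resnum=resnum, resname=resname)
        template = {**_SUGAR_PHOSPHATE_TEMPLATE, **_BASE_TEMPLATES[resname]}
        theta = step * twist
        for name in _nucleotide_atoms(resname, five_prime):
            r, phi, z = template[name]
            if mirror:
                phi, z = _STRAND_B_OFFSET - phi, -z
            x, y, zz = _cyl(r, phi + theta, z)
            model.add_atom(
                key,
                AtomRecord(name=name, element=element_of(name), coords=(x, y, zz + step * rise)),
            )

    for i, base in enumerate(sequence):
        place("A", i + 1, "D" + base, step=i, mirror=False, five_prime=(i == 0))
    # chain B 5'->3' runs antiparallel: its j-th residue pairs with A's (n-1-j)-th
    for j in range(n):
        i = n - 1 - j
        base = COMPLEMENT[sequence[i]]
        place("B", j + 1, "D" + base, step=i, mirror=True, five_prime=(j == 0))
    return model


# --------------------------------------------------------------------------
# posed residues
# --------------------------------------------------------------------------

_STEP = 1.2  # A between successive atoms along the pose axis
_LATERAL = 0.45  # A zig-zag amplitude (keeps backbones non-collinear)


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _posed_residue(
    resname: str, contact_atom: str, tip: np.ndarray, u: np.ndarray, roll: float
) -> list[AtomRecord]:
    """Stylised residue: ``contact_atom`` exactly at ``tip``, the remaining
    canonical atoms retreating along ``u`` with a small zig-zag."""
    names = list(heavy_atom_set(resname))
    if contact_atom not in names:
        raise ValueError(f"{contact_atom!r} is not a heavy atom of {resname}")
    # distal side-chain atoms sit near the tip (as bonded neighbours would);
    # CB and the polar backbone retreat farthest so they cannot shadow the
    # planted pair with extra donor/acceptor or carbon-carbon contacts
    side = [nm for nm in reversed(SIDECHAIN_ATOMS[resname]) if nm != contact_atom]
    backbone = [nm for nm in ("CA", "C", "N", "O") if nm != contact_atom]
    ordered = [contact_atom] + side + backbone
    e1, e2 = _perp_basis(u)
    e1r = math.cos(roll) * e1 + math.sin(roll) * e2
    e2r = -math.sin(roll) * e1 + math.cos(roll) * e2
    atoms = []
    for k, name in enumerate(ordered):
        if k == 0:
            xyz = tip
        else:
            xyz = (
                tip
                + (_STEP * k) * u
                + (_LATERAL * math.cos(1.9 * k)) * e1r
                + (_LATERAL * math.sin(1.9 * k)) * e2r
            )
        atoms.append(
            AtomRecord(
                name=name,
                element=element_of(name),
                coords=tuple(float(v) for v in np.asarray(xyz)),
            )
        )
    return atoms


# Default contact atom per (residue, contact class).
_CONTACT_ATOM: dict[tuple[str, str], str] = {
    ("LYS", "salt_bridge"): "NZ",
    ("ARG", "salt_bridge"): "NH1",
    ("HIS", "salt_bridge"): "NE2",
    ("ASP", "salt_bridge"): "OD1",
    ("GLU", "salt_bridge"): "OE1",
    ("SER", "hydrogen_bond"): "OG",
    ("THR", "hydrogen_bond"): "OG1",
    ("TYR", "hydrogen_bond"): "OH",
    ("ASN", "hydrogen_bond"): "ND2",
    ("GLN", "hydrogen_bond"): "NE2",
    ("LYS", "hydrogen_bond"): "NZ",
    ("ARG", "hydrogen_bond"): "NH1",
    ("TRP", "hydrogen_bond"): "NE1",
    ("VAL", "nonpolar"): "CG1",
    ("LEU", "nonpolar"): "CD1",
    ("ILE", "nonpolar"): "CD1",
    ("ALA", "nonpolar"): "CB",
    ("MET", "nonpolar"): "CE",
    ("THR", "nonpolar"): "CG2",
    ("PHE", "nonpolar"): "CZ",
    ("LYS", "proximity"): "NZ",
    ("ARG", "proximity"): "NH1",
}


def _default_contact_atom(resname: str, contact_class: str) -> str:
    atom = _CONTACT_ATOM.get((resname, contact_class))
    if atom is None and contact_class == "proximity":
        return "N"
    if atom is None:
        raise ValueError(f"no default {contact_class} atom for {resname}; specify protein_atom")
    return atom


def _dna_candidate_atoms(
    resname: str, moiety: str, contact_class: str, protein_resname: str, protein_atom: str
) -> list[str]:
    """DNA atom names in ``resname`` able to realise the requested contact."""
    if moiety == "phosphate":
        pool = ["OP1", "OP2", "O5'", "O3'", "P"]
    elif moiety == "sugar":
        pool = ["O4'", "C1'", "C2'", "C3'", "C4'", "C5'"]
    elif moiety == "base":
        pool = list(BASE_ATOMS[resname])
    else:
        raise ValueError(f"unknown moiety {moiety!r}")
    if contact_class == "salt_bridge":
        if moiety != "phosphate":
            raise ValueError("salt bridges require a phosphate-oxygen target")
        return ["OP1", "OP2"]
    if contact_class == "hydrogen_bond":
        out = []
        for name in pool:
            if element_of(name) not in "NO":
                continue
            if is_donor(protein_resname, protein_atom) and is_acceptor(resname, name):
                out.append(name)
            elif is_acceptor(protein_resname, protein_atom) and is_donor(resname, name):
                out.append(name)
        return out
    if contact_class == "nonpolar":
        return [name for name in pool if element_of(name) == "C"]
    if contact_class == "proximity":
        # carbon targets cannot classify against the N/O tip at any distance
        return [name for name in pool if element_of(name) == "C"]
    raise ValueError(f"unknown contact class {contact_class!r}")


# --------------------------------------------------------------------------
# toy complexes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedContact:
    resname: str
    contact_class: str  # salt_bridge | hydrogen_bond | nonpolar | proximity
    dna_moiety: str  # phosphate | sugar | base
    distance: float
    resnum: int | None = None
    protein_atom: str | None = None
    target_resname: str | None = None  # e.g. "DA" to demand an adenine target


@dataclass(frozen=True)
class NetworkPlant:
    """One intra-protein edge: a child residue posed off an anchor residue.

    ``parent_resnum`` None places the child free-standing (beyond clearance
    from the DNA); otherwise the child's ``child_atom`` is set ``distance``
    away from the parent's ``parent_atom`` so exactly that pair classifies.
    """

    resname: str
    resnum: int
    contact_class: str
    parent_resnum: int | None = None
    parent_atom: str | None = None
    child_atom: str | None = None
    distance: float = 2.9


@dataclass(frozen=True)
class ComplexSpec:
    dna_sequence: str = "AGGCAAAT"
    planted: tuple[PlantedContact, ...] = ()
    network: tuple[NetworkPlant, ...] = ()
    n_decoys: int = 0
    clearance: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.clearance <= DEFAULT_CUTOFFS.interface + 1.0:
            raise ValueError("decoy clearance must exceed the interface cutoff + 1 A")


@dataclass
class ToyComplexTruth:
    contacts: list[dict] = field(default_factory=list)  # resnum, resname, class, moiety, distance
    network_edges: list[dict] = field(default_factory=list)  # resnum_a, resnum_b, class
    decoy_resnums: list[int] = field(default_factory=list)

    def contact_for(self, resnum: int) -> dict | None:
        for c in self.contacts:
            if c["resnum"] == resnum:
                return c
        return None


_MOIETY_PRIORITY = {"base": 0, "sugar": 1, "phosphate": 2}
_DIRECTIONS = [(1.0, 0.0), (0.8, 0.6), (0.8, -0.6), (0.5, 0.87), (0.5, -0.87), (0.0, 1.0), (0.0, -1.0)]
_AZIMUTHS = [0.0, 0.44, -0.44, 0.87, -0.87]
_ROLLS = [0.0, 1.05, 2.09, 3.14, 4.19, 5.24]
_MIN_RESIDUE_SEPARATION = 6.0


def _dna_table(model: StructureModel):
    keys, names, xyz = [], [], []
    for cid in ("A", "B"):
        for key in model.chains[cid]:
            for atom in model.atoms(key):
                keys.append(key)
                names.append(atom.name)
                xyz.append(atom.coords)
    return keys, names, np.asarray(xyz, float)


def _classified_vs_dna(
    atoms: list[AtomRecord], dna_keys, dna_names, dna_xyz, cutoffs: ContactCutoffs, resname: str
):
    xyz = np.array([a.coords for a in atoms])
    d = cdist(xyz, dna_xyz)
    hits = []
    max_cut = max(cutoffs.hydrogen_bond, cutoffs.salt_bridge, cutoffs.nonpolar)
    for i, j in zip(*np.nonzero(d <= max_cut)):
        cls = classify_contact(
            resname, atoms[i].name, dna_keys[j].resname, dna_names[j], float(d[i, j]), cutoffs
        )
        if cls is not None:
            hits.append((i, int(j), cls, chemdata.dna_moiety(dna_names[j], dna_keys[j].resname)))
    return d, hits


def _protein_xyz(placed: dict[int, list[AtomRecord]], exclude: set[int] = frozenset()) -> np.ndarray:
    rows = [a.coords for rn, atoms in placed.items() if rn not in exclude for a in atoms]
    return np.asarray(rows, float) if rows else np.empty((0, 3))


def _validate_dna_plant(
    atoms: list[AtomRecord],
    plant: PlantedContact,
    target_index: int,
    dna_keys,
    dna_names,
    dna_xyz,
    placed,
    cutoffs: ContactCutoffs,
) -> bool:
    d, hits = _classified_vs_dna(atoms, dna_keys, dna_names, dna_xyz, cutoffs, plant.resname)
    dmin = float(d.min())
    if abs(dmin - plant.distance) > 5e-3:
        return False
    i_min, j_min = np.unravel_index(int(d.argmin()), d.shape)
    if i_min != 0 or int(j_min) != target_index:
        return False
    if plant.contact_class == "proximity":
        # the residue must stay out of the interface: its minimum distance is
        # the planted one, so any residual classified pair sits beyond it and
        # cannot create a membership call
        if any(float(d[i, j]) < plant.distance - 5e-3 for i, j, _, _ in hits):
            return False
    else:
        # the planted pair must be the unique minimum and every classified
        # contact of the residue must carry exactly the planted label
        if not hits:
            return False
        labels = {(cls, moiety) for _, _, cls, moiety in hits}
        if labels != {(plant.contact_class, plant.dna_moiety)}:
            return False
        if (0, target_index, plant.contact_class, plant.dna_moiety) not in hits:
            return False
    other = _protein_xyz(placed)
    if len(other):
        if cdist(np.array([a.coords for a in atoms]), other).min() < _MIN_RESIDUE_SEPARATION:
            return False
    return True


def _place_dna_plant(
    plant: PlantedContact,
    model: StructureModel,
    placed: dict[int, list[AtomRecord]],
    used_targets: set[tuple[str, int]],
    rng: np.random.Generator,
    cutoffs: ContactCutoffs,
) -> tuple[list[AtomRecord], np.ndarray, dict]:
    dna_keys, dna_names, dna_xyz = _dna_table(model)
    protein_atom = plant.protein_atom or _default_contact_atom(plant.resname, plant.contact_class)
    nucleotide_slots = []
    for cid in ("A", "B"):
        for key in model.chains[cid]:
            if plant.target_resname and key.resname != plant.target_resname:
                continue
            if (key.chain_id, key.resnum) in used_targets:
                continue
            nucleotide_slots.append(key)
    order = rng.permutation(len(nucleotide_slots))
    for slot_idx in order:
        key = nucleotide_slots[slot_idx]
        candidates = _dna_candidate_atoms(
            key.resname, plant.dna_moiety, plant.contact_class, plant.resname, protein_atom
        )
        for atom_name in candidates:
            target = model.atom(key, atom_name)
            if target is None:  # 5' terminus lacks the phosphate
                continue
            p = target.xyz
            j = next(
                idx
                for idx, (k, nm) in enumerate(zip(dna_keys, dna_names))
                if k == key and nm == atom_name
            )
            radial = np.array([p[0], p[1], 0.0])
            nr = np.linalg.norm(radial)
            radial = radial / nr if nr > 1e-9 else np.array([1.0, 0.0, 0.0])
            zhat = np.array([0.0, 0.0, 1.0])
            for a, b in _DIRECTIONS:
                for az in _AZIMUTHS:
                    ca, sa = math.cos(az), math.sin(az)
                    rot = np.array(
                        [radial[0] * ca - radial[1] * sa, radial[0] * sa + radial[1] * ca, 0.0]
                    )
                    u = a * rot + b * zhat
                    nu = np.linalg.norm(u)
                    if nu < 1e-9:
                        continue
                    u = u / nu
                    for roll in _ROLLS:
                        tip = p + plant.distance * u
                        atoms = _posed_residue(plant.resname, protein_atom, tip, u, roll)
                        if _validate_dna_plant(
                            atoms, plant, j, dna_keys, dna_names, dna_xyz, placed, cutoffs
                        ):
                            used_targets.add((key.chain_id, key.resnum))
                            truth = {
                                "resnum": plant.resnum,
                                "resname": plant.resname,
                                "contact_class": plant.contact_class,
                                "dna_moiety": plant.dna_moiety,
                                "distance": plant.distance,
                                "protein_atom": protein_atom,
                                "dna_residue": f"{key.chain_id}{key.resnum}",
                                "dna_atom": atom_name,
                            }
                            return atoms, u, truth
    raise RuntimeError(
        f"infeasible pose for planted contact {plant.resname}{plant.resnum} "
        f"({plant.contact_class}/{plant.dna_moiety} at {plant.distance} A)"
    )


def _validate_network_child(
    atoms: list[AtomRecord],
    plant: NetworkPlant,
    parent_atoms: list[AtomRecord] | None,
    placed: dict[int, list[AtomRecord]],
    dna_xyz: np.ndarray,
    clearance: float,
    cutoffs: ContactCutoffs,
    parent_resname: str | None,
) -> bool:
    xyz = np.array([a.coords for a in atoms])
    if cdist(xyz, dna_xyz).min() <= clearance:
        return False
    exclude = {plant.parent_resnum} if plant.parent_resnum is not None else set()
    other = _protein_xyz(placed, exclude=exclude)
    # non-parent residues only need to stay beyond every class cutoff so no
    # spurious edge can classify; dense clusters (e.g. a linker triad) are legal
    if len(other) and cdist(xyz, other).min() <= DEFAULT_CUTOFFS.nonpolar + 0.1:
        return False
    if parent_atoms is None:
        return True
    pxyz = np.array([a.coords for a in parent_atoms])
    d = cdist(xyz, pxyz)
    max_cut = max(cutoffs.hydrogen_bond, cutoffs.salt_bridge, cutoffs.nonpolar)
    hits = []
    for i, j in zip(*np.nonzero(d <= max_cut)):
        cls = classify_pair(
            plant.resname, atoms[i].name, parent_resname, parent_atoms[j].name, float(d[i, j]), cutoffs
        )
        if cls is not None:
            hits.append((atoms[i].name, parent_atoms[j].name, cls))
    return hits == [(plant.child_atom, plant.parent_atom, plant.contact_class)]


def _place_network_plant(
    plant: NetworkPlant,
    placed: dict[int, list[AtomRecord]],
    axes: dict[int, np.ndarray],
    resnames: dict[int, str],
    dna_xyz: np.ndarray,
    clearance: float,
    rng: np.random.Generator,
    cutoffs: ContactCutoffs,
) -> tuple[list[AtomRecord], np.ndarray]:
    child_atom = plant.child_atom or _default_contact_atom(plant.resname, plant.contact_class)
    plant = NetworkPlant(**{**plant.__dict__, "child_atom": child_atom})
    if plant.parent_resnum is None:
        # free-standing residue outside the interface shell
        rmax = float(np.linalg.norm(dna_xyz[:, :2], axis=1).max())
        zlo, zhi = float(dna_xyz[:, 2].min()), float(dna_xyz[:, 2].max())
        for _ in range(200):
            phi = rng.uniform(0, 2 * math.pi)
            radial = np.array([math.cos(phi), math.sin(phi), 0.0])
            tip = radial * (rmax + clearance + 2.0 + rng.uniform(0, 4.0))
            tip[2] = rng.uniform(zlo, zhi)
            atoms = _posed_residue(plant.resname, child_atom, tip, radial, rng.uniform(0, 2 * math.pi))
            if _validate_network_child(
                atoms, plant, None, placed, dna_xyz, clearance, cutoffs, None
            ):
                return atoms, radial
        raise RuntimeError(f"could not place free residue {plant.resname}{plant.resnum}")
    parent_atoms = placed[plant.parent_resnum]
    parent_resname = resnames[plant.parent_resnum]
    anchor = next((a for a in parent_atoms if a.name == plant.parent_atom), None)
    if anchor is None:
        raise ValueError(
            f"parent residue {plant.parent_resnum} has no atom {plant.parent_atom!r}"
        )
    u_p = axes[plant.parent_resnum]
    e1, e2 = _perp_basis(u_p)
    # candidate directions fan outward around the parent's own pose axis
    tilt_az = [
        (t, k * math.pi / 6)
        for t in (1.6, 1.3, 1.9, 1.0, 2.2, 0.7)
        for k in range(12)
    ]
    for tilt, az in [(1.6, 0.0)] + tilt_az:
        v = math.cos(tilt) * u_p + math.sin(tilt) * (math.cos(az) * e1 + math.sin(az) * e2)
        v = v / np.linalg.norm(v)
        for roll in _ROLLS:
            tip = anchor.xyz + plant.distance * v
            atoms = _posed_residue(plant.resname, child_atom, tip, v, roll)
            if _validate_network_child(
                atoms, plant, parent_atoms, placed, dna_xyz, clearance, cutoffs, parent_resname
            ):
                return atoms, v
    raise RuntimeError(
        f"infeasible pose for network plant {plant.resname}{plant.resnum} "
        f"on parent {plant.parent_resnum}"
    )


def generate_toy_complex(spec: ComplexSpec) -> tuple[StructureModel, ToyComplexTruth]:
    """Build a toy complex realising a :class:`ComplexSpec`; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    cutoffs = DEFAULT_CUTOFFS
    model = generate_ideal_bdna(spec.dna_sequence)
    truth = ToyComplexTruth()
    placed: dict[int, list[AtomRecord]] = {}
    axes: dict[int, np.ndarray] = {}
    resnames: dict[int, str] = {}
    used_targets: set[tuple[str, int]] = set()

    planted = []
    for k, p in enumerate(spec.planted):
        planted.append(p if p.resnum is not None else PlantedContact(**{**p.__dict__, "resnum": 10 * (k + 1)}))
    seen = [p.resnum for p in planted] + [n.resnum for n in spec.network]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate residue numbers across planted entries")

    # scarce geometry first: base, then sugar, then phosphate targets
    for plant in sorted(planted, key=lambda p: (_MOIETY_PRIORITY[p.dna_moiety], p.resnum)):
        atoms, axis, entry = _place_dna_plant(plant, model, placed, used_targets, rng, cutoffs)
        placed[plant.resnum] = atoms
        axes[plant.resnum] = axis
        resnames[plant.resnum] = plant.resname
        truth.contacts.append(entry)

    _, _, dna_xyz = _dna_table(model)
    for plant in spec.network:
        if plant.parent_resnum is not None and plant.parent_resnum not in placed:
            raise ValueError(f"network plant {plant.resnum} names unplaced parent {plant.parent_resnum}")
        atoms, axis = _place_network_plant(
            plant, placed, axes, resnames, dna_xyz, spec.clearance, rng, cutoffs
        )
        placed[plant.resnum] = atoms
        axes[plant.resnum] = axis
        resnames[plant.resnum] = plant.resname
        if plant.parent_resnum is not None:
            truth.network_edges.append(
                {
                    "resnum_a": min(plant.resnum, plant.parent_resnum),
                    "resnum_b": max(plant.resnum, plant.parent_resnum),
                    "contact_class": plant.contact_class,
                }
            )

    next_num = (max(placed) if placed else 0) + 100
    rmax = float(np.linalg.norm(dna_xyz[:, :2], axis=1).max())
    zlo, zhi = float(dna_xyz[:, 2].min()), float(dna_xyz[:, 2].max())
    decoy_palette = ["LEU", "ALA", "PHE", "GLY", "MET", "ILE", "PRO", "TRP"]
    for k in range(spec.n_decoys):
        resnum = next_num + 10 * k
        resname = decoy_palette[int(rng.integers(len(decoy_palette)))]
        ok = False
        for _ in range(100):
            phi = rng.uniform(0, 2 * math.pi)
            radial = np.array([math.cos(phi), math.sin(phi), 0.0])
            tip = radial * (rmax + spec.clearance + 1.0 + rng.uniform(0, 4.0))
            tip[2] = rng.uniform(zlo, zhi)
            contact = "CB" if resname != "GLY" else "CA"
            atoms = _posed_residue(resname, contact, tip, radial, rng.uniform(0, 2 * math.pi))
            xyz = np.array([a.coords for a in atoms])
            if cdist(xyz, dna_xyz).min() <= spec.clearance:
                continue
            other = _protein_xyz(placed)
            if len(other) and cdist(xyz, other).min() < _MIN_RESIDUE_SEPARATION:
                continue
            ok = True
            break
        if not ok:
            raise RuntimeError(f"could not place decoy residue #{k}")
        placed[resnum] = atoms
        resnames[resnum] = resname
        truth.decoy_resnums.append(resnum)

    for resnum in sorted(placed):
        key = ResidueKey(chain_id="P", resnum=resnum, resname=resnames[resnum])
        for atom in placed[resnum]:
            model.add_atom(key, atom)
    return model, truth


# --------------------------------------------------------------------------
# alignments
# --------------------------------------------------------------------------

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MsaSpec:
    n_orthologs: int = 12
    n_paralogs: int = 16
    reference: str | None = None  # explicit reference sequence
    ref_length: int = 120  # used when reference is None
    ortholog_variable_positions: tuple[int, ...] = ()
    # position -> substitutes; every non-reference paralog differs, cycling the set
    paralog_substitutions: dict[int, tuple[str, ...]] = field(default_factory=dict)
    # position -> (substitutes, n_rows) for partial paralog replacement
    paralog_partial: dict[int, tuple[tuple[str, ...], int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_orthologs < 2 or self.n_paralogs < 2:
            raise ValueError("need at least 2 sequences per alignment")


@dataclass
class MsaTruth:
    variable_positions: tuple[int, ...]
    paralog_substitute_sets: dict[int, frozenset[str]]
    unique_positions: tuple[int, ...]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA_ALPHABET), size=length))


def generate_family_msa(spec: MsaSpec) -> tuple[AlignmentSet, AlignmentSet, MsaTruth]:
    """Ortholog and paralog alignments with planted variation; gap-free."""
    rng = np.random.default_rng(spec.seed)
    if spec.reference is None:
        # auto-generated reference: steer clear of planted substitute residues
        chars = list(_random_protein(rng, spec.ref_length))
        planted = dict(spec.paralog_substitutions)
        for pos, (subs, _) in spec.paralog_partial.items():
            planted.setdefault(pos, subs)
        for pos, subs in planted.items():
            if 1 <= pos <= len(chars) and chars[pos - 1] in subs:
                chars[pos - 1] = next(a for a in _AA_ALPHABET if a not in subs)
        ref = "".join(chars)
    else:
        ref = spec.reference
    L = len(ref)

    def check_positions(positions):
        for p in positions:
            if not 1 <= p <= L:
                raise ValueError(f"planted position {p} outside reference length {L}")

    check_positions(spec.ortholog_variable_positions)
    check_positions(spec.paralog_substitutions)
    check_positions(spec.paralog_partial)
    for pos, subs in spec.paralog_substitutions.items():
        for s in subs:
            if s == ref[pos - 1]:
                raise ValueError(f"substitution at {pos} equals the reference residue {s!r}")

    # orthologs: reference plus n-1 rows varying only at the planted positions
    ortho_rows = [list(ref) for _ in range(spec.n_orthologs)]
    for pos in spec.ortholog_variable_positions:
        n_sub = int(rng.integers(1, spec.n_orthologs))  # at least one row differs
        rows = rng.choice(np.arange(1, spec.n_orthologs), size=n_sub, replace=False)
        for r in rows:
            choices = [a for a in _AA_ALPHABET if a != ref[pos - 1]]
            ortho_rows[int(r)][pos - 1] = str(rng.choice(choices))

    # paralogs: reference plus rows carrying the substitution map
    para_rows = [list(ref) for _ in range(spec.n_paralogs)]
    for pos, subs in spec.paralog_substitutions.items():
        if spec.n_paralogs - 1 < len(subs):
            raise ValueError(f"not enough paralogs to realise all substitutes at {pos}")
        for r in range(1, spec.n_paralogs):
            para_rows[r][pos - 1] = subs[(r - 1) % len(subs)]
    for pos, (subs, n_rows) in spec.paralog_partial.items():
        if n_rows > spec.n_paralogs - 1:
            raise ValueError(f"partial substitution at {pos} exceeds paralog count")
        for s in subs:
            if s == ref[pos - 1]:
                raise ValueError(f"substitution at {pos} equals the reference residue {s!r}")
        rows = rng.choice(np.arange(1, spec.n_paralogs), size=n_rows, replace=False)
        for k, r in enumerate(rows):
            para_rows[int(r)][pos - 1] = subs[k % len(subs)]

    ortho = AlignmentSet(
        ids=["REF"] + [f"ortholog_{i:02d}" for i in range(1, spec.n_orthologs)],
        sequences=["".join(r) for r in ortho_rows],
        reference_id="REF",
    )
    para = AlignmentSet(
        ids=["REF"] + [f"paralog_{i:02d}" for i in range(1, spec.n_paralogs)],
        sequences=["".join(r) for r in para_rows],
        reference_id="REF",
    )
    unique = tuple(
        sorted(set(spec.paralog_substitutions) - set(spec.ortholog_variable_positions))
    )
    truth = MsaTruth(
        variable_positions=tuple(sorted(spec.ortholog_variable_positions)),
        paralog_substitute_sets={
            pos: frozenset(subs) for pos, subs in spec.paralog_substitutions.items()
        },
        unique_positions=unique,
    )
    return ortho, para, truth


# --------------------------------------------------------------------------
# phenotype tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeSpec:
    n_mutants: int = 90
    n_defective: int = 34
    defective_fraction_range: tuple[float, float] = (0.0, 0.2)
    wt_mean: float = 100.0
    n_replicates: int = 3
    dispersion: float = 0.2  # fractional variance excess over Poisson
    # optional explicit plan: mutant label -> (position, true fraction)
    plan: dict[str, tuple[int, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.defective_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("effect fractions must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")


@dataclass
class PhenotypeTruth:
    defective: dict[str, float]  # label -> planted fraction
    normal: tuple[str, ...]


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial counts with variance (1 + dispersion) * mean."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if dispersion <= 0:
        return rng.poisson(mean, size)
    p = 1.0 / (1.0 + dispersion)
    n = mean / dispersion
    return rng.negative_binomial(n, p, size)


def generate_phenotype_table(
    spec: PhenotypeSpec,
) -> tuple[list[PhenotypeRecord], PhenotypeTruth]:
    """Simulated alanine-scan table (WT + mutants) with planted defect fractions."""
    rng = np.random.default_rng(spec.seed)
    if spec.plan is not None:
        plan = dict(spec.plan)
    else:
        if spec.n_defective > spec.n_mutants:
            raise ValueError("more defective mutants than mutants")
        positions = np.sort(rng.choice(np.arange(1, 353), size=spec.n_mutants, replace=False))
        letters = rng.choice(list("STYKR"), size=spec.n_mutants)
        defective_idx = set(
            int(i) for i in rng.choice(spec.n_mutants, size=spec.n_defective, replace=False)
        )
        lo, hi = spec.defective_fraction_range
        plan = {}
        for i, (pos, aa) in enumerate(zip(positions, letters)):
            frac = float(rng.uniform(lo, hi)) if i in defective_idx else 1.0
            plan[f"{aa}{int(pos)}A"] = (int(pos), frac)
    records = [
        PhenotypeRecord(
            mutant="WT",
            positions=(),
            counts=tuple(
                int(c) for c in _nb_counts(rng, spec.wt_mean, spec.dispersion, spec.n_replicates)
            ),
        )
    ]
    defective: dict[str, float] = {}
    normal: list[str] = []
    for label, (pos, frac) in plan.items():
        counts = _nb_counts(rng, frac * spec.wt_mean, spec.dispersion, spec.n_replicates)
        records.append(
            PhenotypeRecord(mutant=label, positions=(pos,), counts=tuple(int(c) for c in counts))
        )
        if frac < 0.5:
            defective[label] = frac
        else:
            normal.append(label)
    return records, PhenotypeTruth(defective=defective, normal=tuple(normal))


# --------------------------------------------------------------------------
# paper-like presets (synthetic stand-ins, mOct4 numbering)
# --------------------------------------------------------------------------

# K/R residues hydrogen-bonded/salt-bridged to the DNA backbone.
_PRESET_KR = (150, 179, 192, 227, 247, 268, 275, 277, 279)
_PRESET_KR_NAMES = {150: "ARG", 179: "ARG", 192: "LYS", 227: "ARG", 247: "LYS",
                    268: "ARG", 275: "ARG", 277: "LYS", 279: "LYS"}
# S/T residues: backbone contacts except T175, which reads a base.
_PRESET_ST = {173: ("SER", "phosphate"), 175: ("THR", "base"), 176: ("THR", "phosphate"),
              186: ("SER", "phosphate"), 228: ("THR", "phosphate")}


def paper_like_complex(seed: int = 0) -> tuple[StructureModel, ToyComplexTruth]:
    """Synthetic POU-like complex: an idealised PORE-bearing duplex with the
    functionally characterised interface residues planted at their murine
    Oct4 positions, a 4.4 A near-miss lysine, and the intra-molecular
    clusters (E181-Q157/R150, V269-N273, K215-Q211-Y155, D159-T156) planted
    as residue-residue contacts. A stand-in for demonstration — not a
    crystal structure.
    """
    planted = [
        PlantedContact("LYS", "proximity", "sugar", 4.4, resnum=147),
    ]
    for pos in _PRESET_KR:
        planted.append(PlantedContact(_PRESET_KR_NAMES[pos], "salt_bridge", "phosphate", 2.8, resnum=pos))
    for pos, (resname, moiety) in _PRESET_ST.items():
        planted.append(PlantedContact(resname, "hydrogen_bond", moiety, 3.0, resnum=pos))
    planted.append(PlantedContact("GLN", "hydrogen_bond", "base", 3.0, resnum=174, target_resname="DA"))
    planted.append(PlantedContact("ASN", "hydrogen_bond", "base", 3.0, resnum=273, target_resname="DA"))
    network = (
        NetworkPlant("GLU", 181, "salt_bridge", parent_resnum=150, parent_atom="NE", child_atom="OE1", distance=3.4),
        NetworkPlant("GLN", 157, "hydrogen_bond", parent_resnum=181, parent_atom="OE2", child_atom="NE2", distance=2.9),
        NetworkPlant("VAL", 269, "hydrogen_bond", parent_resnum=273, parent_atom="O", child_atom="N", distance=2.9),
        NetworkPlant("TYR", 155, "hydrogen_bond", parent_resnum=None),
        NetworkPlant("GLN", 211, "hydrogen_bond", parent_resnum=155, parent_atom="OH", child_atom="NE2", distance=2.9),
        NetworkPlant("LYS", 215, "hydrogen_bond", parent_resnum=211, parent_atom="O", child_atom="NZ", distance=2.9),
        NetworkPlant("ASP", 159, "salt_bridge", parent_resnum=215, parent_atom="NZ", child_atom="OD1", distance=3.2),
        NetworkPlant("THR", 156, "hydrogen_bond", parent_resnum=159, parent_atom="O", child_atom="OG1", distance=2.8),
    )
    spec = ComplexSpec(
        dna_sequence="AGGCAAAT" * 3,  # PORE sequence tiled for spacing
        planted=tuple(planted),
        network=network,
        n_decoys=4,
        seed=seed,
    )
    return generate_toy_complex(spec)


def paper_like_msas(seed: int = 0) -> tuple[AlignmentSet, AlignmentSet, MsaTruth]:
    """Ortholog (12 species) and murine-paralog (16 members) alignments that
    emulate the published supplementary alignments: 7 variable positions
    among the orthologs; K170 replaced by N/V/P/S and K215 by S/T/L/P/D
    across the paralogs. Synthetic sequences, not database accessions.
    """
    rng = np.random.default_rng(seed)
    ref = list(_random_protein(rng, 250))
    ref[170 - 1] = "K"
    ref[215 - 1] = "K"
    for pos, aa in ((216, "S"), (237, "S"), (240, "T"), (244, "K")):
        ref[pos - 1] = aa
    ref[224 - 1] = "A"
    spec = MsaSpec(
        n_orthologs=12,
        n_paralogs=16,
        reference="".join(ref),
        ortholog_variable_positions=(141, 166, 216, 224, 237, 240, 244),
        paralog_substitutions={
            170: ("N", "V", "P", "S"),
            215: ("S", "T", "L", "P", "D"),
            224: ("G",),  # fully substituted in paralogs but ortholog-variable: never unique
        },
        paralog_partial={160: (("R",), 5), 205: (("Q", "H"), 7)},
        seed=seed,
    )
    return generate_family_msa(spec)


def paper_like_phenotype_spec(seed: int = 0) -> PhenotypeSpec:
    """90-mutant plan: 33 defective sites inside the POU domain (fractions
    <= 0.2), one defective site outside it (Y327A at 0.45x WT), 56 normal."""
    rng = np.random.default_rng(seed)
    structural = {
        147: "K", 150: "R", 155: "Y", 156: "T", 157: "Q", 159: "D", 173: "S",
        174: "Q", 175: "T", 176: "T", 179: "R", 181: "E", 186: "S", 192: "K",
        211: "Q", 215: "K", 227: "R", 228: "T", 247: "K", 268: "R", 269: "V",
        273: "N", 275: "R", 277: "K", 279: "K",
    }
    pou_lo, pou_hi = 131, 289
    plan: dict[str, tuple[int, float]] = {}
    used = set(structural) | {327}
    for pos, aa in sorted(structural.items()):
        plan[f"{aa}{pos}A"] = (pos, float(rng.uniform(0.0, 0.2)))
    filler_pool = [p for p in range(pou_lo, pou_hi + 1) if p not in used]
    extra = rng.choice(filler_pool, size=33 - len(structural), replace=False)
    for pos in sorted(int(p) for p in extra):
        plan[f"K{pos}A"] = (pos, float(rng.uniform(0.0, 0.2)))
        used.add(pos)
    plan["Y327A"] = (327, 0.45)
    normal_pool = [p for p in range(1, 353) if p not in used]
    normal_pos = rng.choice(normal_pool, size=90 - len(plan), replace=False)
    for pos in sorted(int(p) for p in normal_pos):
        aa = str(rng.choice(list("STYKR")))
        plan[f"{aa}{pos}A"] = (pos, 1.0)
    return PhenotypeSpec(plan=plan, seed=seed)
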