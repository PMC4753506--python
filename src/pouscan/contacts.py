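"""Protein-DNA interface definition and contact typing.

A residue belongs to the interface when any of its heavy atoms lies within
the membership cutoff (default 3.6 A) of any DNA heavy atom. Each close atom
pair is additionally typed as salt bridge, hydrogen bond or nonpolar contact
using distance-only heavy-atom criteria (the structures carry no hydrogens,
so no angular term is applied):

* salt bridge — charged-group protein atom vs phosphate oxygen, <= 4.0 A;
* hydrogen bond — N/O donor-capable vs acceptor-capable pair, <= 3.5 A;
* nonpolar — carbon vs carbon, <= 4.5 A.

Precedence is salt bridge > hydrogen bond > nonpolar. The membership cutoff
is independent of the per-class cutoffs: a residue can be interface-listed
by a close approach that no class covers; it is then reported as
``unclassified_proximity``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import chemdata
from .chemdata import dna_moiety
from .structure import NumberingMap, ResidueKey, StructureModel

__all__ = [
    "ContactCutoffs",
    "Contact",
    "InterfaceResidue",
    "InterfaceReport",
    "classify_contact",
    "classify_pair",
    "min_distance_to_dna",
    "interface_residues",
    "base_contacts",
]


@dataclass(frozen=True)
class ContactCutoffs:
    interface: float = 3.6
    hydrogen_bond: float = 3.5
    salt_bridge: float = 4.0
    nonpolar: float = 4.5
    near_miss_margin: float = 1.0

    def __post_init__(self):
        if min(self.interface, self.hydrogen_bond, self.salt_bridge, self.nonpolar) <= 0:
            raise ValueError("cutoffs must be positive")


DEFAULT_CUTOFFS = ContactCutoffs()


@dataclass(frozen=True)
class Contact:
    protein_atom: tuple[ResidueKey, str]
    dna_atom: tuple[ResidueKey, str]
    distance: float
    contact_class: str
    dna_moiety: str | None

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")


def _is_charged(resname: str, atom: str) -> bool:
    return atom in chemdata.CHARGED_ATOMS.get(resname, frozenset())


def classify_contact(
    protein_resname: str,
    protein_atom: str,
    dna_resname: str,
    dna_atom: str,
    distance: float,
    cutoffs: ContactCutoffs = DEFAULT_CUTOFFS,
) -> str | None:
    """Type a protein-atom / DNA-atom pair; None when no class applies."""
    if distance < 0:
        raise ValueError("negative distance")
    if (
        _is_charged(protein_resname, protein_atom)
        and dna_atom in chemdata.PHOSPHATE_OXYGENS
        and distance <= cutoffs.salt_bridge
    ):
        return "salt_bridge"
    pe = chemdata.element_of(protein_atom)
    de = chemdata.element_of(dna_atom)
    if pe in "NO" and de in "NO" and distance <= cutoffs.hydrogen_bond:
        donor_acceptor = (
            chemdata.is_donor(protein_resname, protein_atom)
            and chemdata.is_acceptor(dna_resname, dna_atom)
        ) or (
            chemdata.is_acceptor(protein_resname, protein_atom)
            and chemdata.is_donor(dna_resname, dna_atom)
        )
        if donor_acceptor:
            return "hydrogen_bond"
    if pe == "C" and de == "C" and distance <= cutoffs.nonpolar:
        return "nonpolar"
    return None


def classify_pair(
    resname_a: str,
    atom_a: str,
    resname_b: str,
    atom_b: str,
    distance: float,
    cutoffs: ContactCutoffs = DEFAULT_CUTOFFS,
) -> str | None:
    """Type an intra-protein atom pair with the same tables.

    A salt bridge here requires groups of opposite formal sign (basic vs
    acidic side chains); hydrogen-bond and nonpolar rules are unchanged.
    """
    if distance < 0:
        raise ValueError("negative distance")
    basic_a = atom_a in chemdata.BASIC_ATOMS.get(resname_a, frozenset())
    basic_b = atom_b in chemdata.BASIC_ATOMS.get(resname_b, frozenset())
    acidic_a = atom_a in chemdata.ACIDIC_ATOMS.get(resname_a, frozenset())
    acidic_b = atom_b in chemdata.ACIDIC_ATOMS.get(resname_b, frozenset())
    if ((basic_a and acidic_b) or (acidic_a and basic_b)) and distance <= cutoffs.salt_bridge:
        return "salt_bridge"
    ea, eb = chemdata.element_of(atom_a), chemdata.element_of(atom_b)
    if ea in "NO" and eb in "NO" and distance <= cutoffs.hydrogen_bond:
        ok = (
            chemdata.is_donor(resname_a, atom_a) and chemdata.is_acceptor(resname_b, atom_b)
        ) or (
            chemdata.is_acceptor(resname_a, atom_a) and chemdata.is_donor(resname_b, atom_b)
        )
        if ok:
            return "hydrogen_bond"
    if ea == "C" and eb == "C" and distance <= cutoffs.nonpolar:
        return "nonpolar"
    return None


def _dna_atom_table(model: StructureModel):
    keys, names, resnames, xyz = [], [], [], []
    for cid in model.dna_chains():
        for key in model.chains[cid]:
            for atom in model.atoms(key):
                keys.append(key)
                names.append(atom.name)
                resnames.append(key.resname)
                xyz.append(atom.coords)
    return keys, names, resnames, np.asarray(xyz, float)


def min_distance_to_dna(model: StructureModel, residue: ResidueKey) -> float:
    """Minimum heavy-atom distance from one protein residue to any DNA atom."""
    if not model.dna_chains():
        raise ValueError("model has no DNA chain")
    _, _, _, dna_xyz = _dna_atom_table(model)
    d = cdist(model.coords(residue), dna_xyz)
    return float(d.min())


@dataclass
class InterfaceResidue:
    residue: ResidueKey
    ref_position: int
    min_distance: float
    contacts: list[Contact] = field(default_factory=list)

    @property
    def touches_base(self) -> bool:
        return any(c.dna_moiety == "base" for c in self.contacts)

    @property
    def touches_backbone(self) -> bool:
        return any(c.dna_moiety in ("phosphate", "sugar") for c in self.contacts)

    @property
    def contact_classes(self) -> tuple[str, ...]:
        if not self.contacts:
            return ("unclassified_proximity",)
        return tuple(sorted({c.contact_class for c in self.contacts}))


@dataclass
class InterfaceReport:
    cutoff: float
    residues: list[InterfaceResidue]
    near_misses: list[tuple[ResidueKey, int, float]]  # (residue, ref position, distance)

    def find(self, ref_position: int) -> InterfaceResidue | None:
        for r in self.residues:
            if r.ref_position == ref_position:
                return r
        return None

    def positions(self) -> list[int]:
        return [r.ref_position for r in self.residues]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.residues:
            rows.append(
                {
                    "residue": str(r.residue),
                    "chain": r.residue.chain_id,
                    "ref_position": r.ref_position,
                    "resname": r.residue.resname,
                    # distances printed at 1 decimal, half-up (full precision kept internally)
                    "min_distance": _round1(r.min_distance),
                    "classes": ";".join(r.contact_classes),
                    "moieties": ";".join(
                        sorted({c.dna_moiety for c in r.contacts if c.dna_moiety})
                    ),
                    "touches_base": r.touches_base,
                    "touches_backbone": r.touches_backbone,
                    "n_contacts": len(r.contacts),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "residue", "chain", "ref_position", "resname", "min_distance",
                "classes", "moieties", "touches_base", "touches_backbone", "n_contacts",
            ],
        )

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)

    def to_json(self) -> str:
        doc = {
            "cutoff": self.cutoff,
            "residues": self.to_frame().to_dict(orient="records"),
            "near_misses": [
                {"residue": str(k), "ref_position": p, "min_distance": _round1(d)}
                for k, p, d in self.near_misses
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def _round1(x: float) -> float:
    """Round half-up to one decimal (report convention)."""
    return float(np.floor(x * 10 + 0.5) / 10)


def interface_residues(
    model: StructureModel,
    cutoff: float = 3.6,
    cutoffs: ContactCutoffs | None = None,
    numbering: NumberingMap | None = None,
) -> InterfaceReport:
    """All protein residues within ``cutoff`` of DNA, with typed contacts.

    Near misses — residues with minimum distance in (cutoff, cutoff + 1.0] —
    are listed separately with their distances.
    """
    if cutoffs is None:
        cutoffs = ContactCutoffs(interface=cutoff)
    else:
        cutoff = cutoffs.interface
    numbering = numbering or NumberingMap()
    if not model.protein_chains():
        raise ValueError("model has no protein chain")
    dna_keys, dna_names, dna_resnames, dna_xyz = _dna_atom_table(model)
    if len(dna_keys) == 0:
        raise ValueError("model has no DNA chain")
    max_class_cutoff = max(cutoffs.hydrogen_bond, cutoffs.salt_bridge, cutoffs.nonpolar)
    members: list[InterfaceResidue] = []
    near: list[tuple[ResidueKey, int, float]] = []
    for cid in model.protein_chains():
        for key in model.chains[cid]:
            atoms = model.atoms(key)
            d = cdist(model.coords(key), dna_xyz)
            dmin = float(d.min())
            refpos = numbering.ref_position(cid, key.resnum)
            if dmin <= cutoff:
                contacts = []
                for i, j in zip(*np.nonzero(d <= max_class_cutoff)):
                    cls = classify_contact(
                        key.resname, atoms[i].name,
                        dna_resnames[j], dna_names[j],
                        float(d[i, j]), cutoffs,
                    )
                    if cls is not None:
                        contacts.append(
                            Contact(
                                protein_atom=(key, atoms[i].name),
                                dna_atom=(dna_keys[j], dna_names[j]),
                                distance=float(d[i, j]),
                                contact_class=cls,
                                dna_moiety=dna_moiety(dna_names[j], dna_resnames[j]),
                            )
                        )
                members.append(
                    InterfaceResidue(
                        residue=key, ref_position=refpos,
                        min_distance=dmin, contacts=contacts,
                    )
                )
            elif dmin <= cutoff + cutoffs.near_miss_margin:
                near.append((key, refpos, dmin))
    members.sort(key=lambda r: (r.ref_position, r.residue))
    near.sort(key=lambda t: (t[1], t[0]))
    return InterfaceReport(cutoff=cutoff, residues=members, near_misses=near)


def base_contacts(report: InterfaceReport) -> list[InterfaceResidue]:
    """Interface residues with at least one DNA-base contact, in order."""
    return [r for r in report.residues if r.touches_base]
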