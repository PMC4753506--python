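"""Shared fixtures: every structural/alignment/phenotype input is generated
programmatically by the synthetic module at test time."""

from __future__ import annotations

import numpy as np
import pytest

from pouscan.structure import AtomRecord, ResidueKey, StructureModel
from pouscan.synthetic import (
    ComplexSpec,
    NetworkPlant,
    PlantedContact,
    generate_toy_complex,
    paper_like_complex,
    paper_like_msas,
)

# a plant of every contact class plus a near-miss residue
MIXED_PLANTS = (
    PlantedContact("LYS", "salt_bridge", "phosphate", 2.8),
    PlantedContact("SER", "hydrogen_bond", "sugar", 3.0),
    PlantedContact("VAL", "nonpolar", "base", 4.0),
    PlantedContact("GLN", "hydrogen_bond", "base", 3.0),
    PlantedContact("LYS", "proximity", "sugar", 4.4, resnum=99),
)


def mixed_spec(seed: int, n_decoys: int = 3) -> ComplexSpec:
    return ComplexSpec(planted=MIXED_PLANTS, n_decoys=n_decoys, seed=seed)


@pytest.fixture(scope="session")
def toy_complex():
    """(model, truth) with one plant per contact class, decoys, near miss."""
    return generate_toy_complex(mixed_spec(seed=7))


@pytest.fixture(scope="session")
def chain_complex():
    """Toy complex with a planted intra-protein chain A(60)-B(70)-C(80)."""
    spec = ComplexSpec(
        planted=(PlantedContact("ASN", "hydrogen_bond", "base", 3.0, resnum=50),),
        network=(
            NetworkPlant("TYR", 60, "hydrogen_bond", parent_resnum=None),
            NetworkPlant("GLN", 70, "hydrogen_bond", parent_resnum=60,
                         parent_atom="OH", child_atom="NE2", distance=2.9),
            NetworkPlant("SER", 80, "hydrogen_bond", parent_resnum=70,
                         parent_atom="O", child_atom="OG", distance=2.9),
        ),
        seed=11,
    )
    return generate_toy_complex(spec)


@pytest.fixture(scope="session")
def paper_complex():
    return paper_like_complex(seed=0)


@pytest.fixture(scope="session")
def paper_msas():
    return paper_like_msas(seed=0)


def single_atom_residue(chain_id: str, resnum: int, resname: str, atom: str,
                        xyz: tuple[float, float, float]) -> tuple[ResidueKey, AtomRecord]:
    key = ResidueKey(chain_id=chain_id, resnum=resnum, resname=resname)
    from pouscan.chemdata import element_of
    return key, AtomRecord(name=atom, element=element_of(atom), coords=xyz)


def model_from_atoms(entries) -> StructureModel:
    """entries: iterable of (chain_id, resnum, resname, atom_name, xyz)."""
    from pouscan.chemdata import element_of
    model = StructureModel()
    for chain_id, resnum, resname, atom, xyz in entries:
        key = ResidueKey(chain_id=chain_id, resnum=resnum, resname=resname)
        model.add_atom(key, AtomRecord(name=atom, element=element_of(atom), coords=xyz))
    return model


def strip_sidechain(model: StructureModel, chain_id: str, resnum: int,
                    keep=("N", "CA", "C", "O", "CB")) -> StructureModel:
    new = model.copy()
    key = new.find_residue(chain_id, resnum)
    new.chains[chain_id][key] = [a for a in new.chains[chain_id][key] if a.name in keep]
    return new


def max_deviation(model_a: StructureModel, model_b: StructureModel,
                  chain_id: str, resnum: int) -> float:
    ka = model_a.find_residue(chain_id, resnum)
    kb = model_b.find_residue(chain_id, resnum)
    a = {at.name: np.asarray(at.coords) for at in model_a.atoms(ka)}
    b = {at.name: np.asarray(at.coords) for at in model_b.atoms(kb)}
    assert set(a) == set(b)
    return max(float(np.linalg.norm(a[n] - b[n])) for n in a)
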