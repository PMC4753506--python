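import numpy as np
import pytest
from pouscan.chemdata import dna_moiety
from pouscan.contacts import (
    ContactCutoffs,
    base_contacts,
    classify_contact,
    interface_residues,
    min_distance_to_dna,
)
from pouscan.structure import StructureModel
from conftest import model_from_atoms


class TestMinDistance:
    def test_single_pair(self):
        model = model_from_atoms(
            [("P", 1, "LYS", "NZ", (0.0, 0.0, 0.0)), ("D", 1, "DA", "C1'", (0.0, 0.0, 3.5))]
        )
        assert min_distance_to_dna(model, model.find_residue("P", 1)) == pytest.approx(3.5)

    def test_no_dna_chain_is_error(self):
        model = model_from_atoms([("P", 1, "LYS", "NZ", (0.0, 0.0, 0.0))])
        with pytest.raises(ValueError, match="DNA"):
            min_distance_to_dna(model, model.find_residue("P", 1))

    def test_equals_brute_force_double_loop(self, toy_complex):
        model, _ = toy_complex
        for resnum in (10, 20, 30):
            key = model.find_residue("P", resnum)
            best = np.inf
            for atom in model.atoms(key):
                for cid in ("A", "B"):
                    for dkey in model.chains[cid]:
                        for datom in model.atoms(dkey):
                            best = min(best, float(np.linalg.norm(
                                np.asarray(atom.coords) - np.asarray(datom.coords))))
            assert min_distance_to_dna(model, key) == pytest.approx(best, abs=1e-12)


@pytest.mark.parametrize(
    "atom,resname,expected",
    [
        ("OP1", "DA", "phosphate"),
        ("OP2", "DT", "phosphate"),
        ("P", "DG", "phosphate"),
        ("O5'", "DC", "phosphate"),
        ("O3'", "DA", "phosphate"),  # bridging oxygen counts as phosphodiester
        ("C1'", "DA", "sugar"),
        ("O4'", "DT", "sugar"),
        ("N7", "DA", "base"),
        ("C7", "DT", "base"),
        ("O6", "DG", "base"),
        ("N4", "DC", "base"),
    ],
)
def test_dna_moiety_table(atom, resname, expected):
    assert dna_moiety(atom, resname) == expected


def test_dna_moiety_unknown_atom_rejected():
    with pytest.raises(ValueError, match="unknown atom"):
        dna_moiety("N7", "DC")  # pyrimidines have no N7


@pytest.mark.parametrize(
    "p_res,p_atom,d_res,d_atom,dist,expected",
    [
        ("LYS", "NZ", "DA", "OP1", 2.8, "salt_bridge"),
        ("ARG", "NH1", "DT", "OP2", 3.9, "salt_bridge"),
        # precedence: a charged N/O pair inside both windows is a salt bridge
        ("LYS", "NZ", "DA", "OP1", 3.4, "salt_bridge"),
        ("SER", "OG", "DA", "O3'", 3.0, "hydrogen_bond"),
        ("THR", "OG1", "DA", "N7", 3.2, "hydrogen_bond"),
        ("GLN", "NE2", "DT", "O4", 3.1, "hydrogen_bond"),
        ("VAL", "CG1", "DT", "C7", 4.2, "nonpolar"),
        ("LEU", "CD1", "DA", "C1'", 4.4, "nonpolar"),
        # beyond every class cutoff
        ("LYS", "NZ", "DA", "OP1", 4.1, None),
        ("SER", "OG", "DA", "O3'", 3.6, None),
        ("VAL", "CG1", "DT", "C7", 4.6, None),
        # donor/donor pair is not a hydrogen bond
        ("LYS", "NZ", "DA", "N6", 3.0, None),
        # carbon/oxygen close approach classifies nowhere
        ("VAL", "CG1", "DA", "OP1", 3.0, None),
    ],
)
def test_classify_contact_rules(p_res, p_atom, d_res, d_atom, dist, expected):
    assert classify_contact(p_res, p_atom, d_res, d_atom, dist) == expected


def test_classify_contact_negative_distance_rejected():
    with pytest.raises(ValueError, match="negative"):
        classify_contact("LYS", "NZ", "DA", "OP1", -1.0)


class TestInterface:
    def test_membership_and_near_miss(self):
        model = model_from_atoms(
            [
                ("P", 1, "LYS", "NZ", (0.0, 0.0, 3.5)),
                ("P", 2, "LYS", "NZ", (0.0, 0.0, 4.0)),
                ("P", 3, "LYS", "NZ", (0.0, 0.0, 9.0)),
                ("D", 1, "DA", "C1'", (0.0, 0.0, 0.0)),
            ]
        )
        report = interface_residues(model, cutoff=3.6)
        assert report.positions() == [1]
        assert [(p, round(d, 1)) for _, p, d in report.near_misses] == [(2, 4.0)]

    def test_interface_without_classified_contact_is_unclassified(self):
        # carbon-nitrogen approach at 3.5 A: inside the membership cutoff,
        # outside every class definition
        model = model_from_atoms(
            [("P", 1, "LYS", "NZ", (0.0, 0.0, 3.5)), ("D", 1, "DA", "C1'", (0.0, 0.0, 0.0))]
        )
        (res,) = interface_residues(model).residues
        assert res.contacts == []
        assert res.contact_classes == ("unclassified_proximity",)

    def test_planted_recovery(self, toy_complex):
        model, truth = toy_complex
        report = interface_residues(model)
        expected = {
            c["resnum"]: (c["contact_class"], c["dna_moiety"])
            for c in truth.contacts
            if c["contact_class"] != "proximity" and c["distance"] <= report.cutoff
        }
        assert set(report.positions()) == set(expected)
        for res in report.residues:
            cls, moiety = expected[res.ref_position]
            assert res.contact_classes == (cls,)
            assert {c.dna_moiety for c in res.contacts} == {moiety}
            planted = next(c for c in truth.contacts if c["resnum"] == res.ref_position)
            assert res.min_distance == pytest.approx(planted["distance"], abs=5e-3)

    def test_near_miss_distance_reported_to_one_decimal(self, toy_complex):
        model, _ = toy_complex
        report = interface_residues(model)
        near = {p: d for _, p, d in report.near_misses}
        assert 99 in near
        assert round(near[99], 1) == 4.4

    def test_decoys_never_reported(self, toy_complex):
        model, truth = toy_complex
        report = interface_residues(model, cutoff=4.0)
        reported = set(report.positions()) | {p for _, p, _ in report.near_misses}
        assert reported.isdisjoint(truth.decoy_resnums)

    def test_cutoff_monotonicity(self, toy_complex):
        model, _ = toy_complex
        small = set(interface_residues(model, cutoff=3.6).positions())
        large = set(interface_residues(model, cutoff=4.0).positions())
        assert small <= large

    def test_chain_order_does_not_matter(self, toy_complex):
        model, _ = toy_complex
        reordered = StructureModel()
        for cid in reversed(list(model.chains)):
            for key, atoms in model.chains[cid].items():
                for a in atoms:
                    reordered.add_atom(key, a)
        a = interface_residues(model)
        b = interface_residues(reordered)
        assert a.positions() == b.positions()
        for ra, rb in zip(a.residues, b.residues):
            assert ra.min_distance == pytest.approx(rb.min_distance, abs=1e-12)
            assert len(ra.contacts) == len(rb.contacts)

    def test_min_distance_bounds_contacts(self, toy_complex):
        model, _ = toy_complex
        for res in interface_residues(model).residues:
            assert all(c.distance >= res.min_distance - 1e-12 for c in res.contacts)

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ContactCutoffs(interface=-1.0)


class TestBaseContacts:
    def test_planted_base_contacts_only(self, toy_complex):
        model, truth = toy_complex
        report = interface_residues(model)
        expected = sorted(
            c["resnum"] for c in truth.contacts
            if c["dna_moiety"] == "base" and c["contact_class"] != "proximity"
            and c["distance"] <= report.cutoff
        )
        assert [r.ref_position for r in base_contacts(report)] == expected

    def test_empty_report_gives_empty_list(self):
        model = model_from_atoms(
            [("P", 1, "LYS", "NZ", (0.0, 0.0, 50.0)), ("D", 1, "DA", "C1'", (0.0, 0.0, 0.0))]
        )
        assert base_contacts(interface_residues(model)) == []

    def test_backbone_flags(self, toy_complex):
        model, truth = toy_complex
        report = interface_residues(model)
        for res in report.residues:
            planted = next(c for c in truth.contacts if c["resnum"] == res.ref_position)
            assert res.touches_base == (planted["dna_moiety"] == "base")
            assert res.touches_backbone == (planted["dna_moiety"] in ("phosphate", "sugar"))


def test_report_serialisation_roundtrip(toy_complex):
    import json

    model, _ = toy_complex
    report = interface_residues(model)
    frame = report.to_frame()
    assert list(frame["ref_position"]) == report.positions()
    doc = json.loads(report.to_json())
    assert doc["cutoff"] == report.cutoff
    assert len(doc["residues"]) == len(report.residues)
    assert report.to_tsv().splitlines()[0].startswith("residue\t")
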