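import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pouscan.structure import AtomRecord, StructureModel, missing_sidechain_residues
from pouscan.superpose import (
    complete_model,
    graft_sidechain,
    kabsch_superpose,
    pair_by_alignment,
)
from pouscan.synthetic import ComplexSpec, PlantedContact, generate_toy_complex

from conftest import max_deviation, model_from_atoms, strip_sidechain


def random_cloud(rng, n=10, scale=5.0):
    return rng.normal(scale=scale, size=(n, 3))


def rigid(rng):
    R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t


class TestKabsch:
    def test_identity_on_equal_sets(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 1.7]])
        rt = kabsch_superpose(pts, pts)
        assert np.allclose(rt.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(rt.translation, 0, atol=1e-12)
        assert rt.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_rotation_and_shift(self):
        rng = np.random.default_rng(1)
        pts = random_cloud(rng)
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([1.0, 2.0, 3.0])
        rt = kabsch_superpose(moved, pts)
        assert rt.rmsd <= 1e-9
        assert np.allclose(rt.apply(moved), pts, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_rmsd_matches_scipy_align_vectors(self, seed):
        # independent oracle: scipy's Wahba solver on the centred clouds
        rng = np.random.default_rng(seed)
        a, b = random_cloud(rng), random_cloud(rng)
        rt = kabsch_superpose(a, b)
        a0, b0 = a - a.mean(0), b - b.mean(0)
        _, rssd = Rotation.align_vectors(b0, a0)
        assert rt.rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-9)

    def test_rmsd_is_least_squares_minimum_by_grid_search(self):
        rng = np.random.default_rng(3)
        a, b = random_cloud(rng, n=8), random_cloud(rng, n=8)
        rt = kabsch_superpose(a, b)
        a0, b0 = a - a.mean(0), b - b.mean(0)
        grid = np.linspace(0, 2 * np.pi, 25)[:-1]
        best = np.inf
        for ex in grid:
            for ey in np.linspace(0, np.pi, 13):
                for ez in grid:
                    R = Rotation.from_euler("zyz", [ex, ey, ez]).as_matrix()
                    best = min(best, np.sqrt(np.mean(np.sum((a0 @ R.T - b0) ** 2, axis=1))))
        assert rt.rmsd <= best + 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_rmsd_invariant_under_rigid_pretransform(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_cloud(rng), random_cloud(rng)
        base = kabsch_superpose(a, b).rmsd
        R1, t1 = rigid(rng)
        R2, t2 = rigid(rng)
        moved = kabsch_superpose(a @ R1.T + t1, b @ R2.T + t2).rmsd
        assert moved == pytest.approx(base, abs=1e-6)

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.ones((2, 3)))

    def test_rejects_collinear_sets(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(5)
        rt = kabsch_superpose(random_cloud(rng), random_cloud(rng))
        assert np.linalg.det(rt.rotation) == pytest.approx(1.0, abs=1e-9)


def _protein_pair(template_missing: int | None = None):
    """Two 6-residue chains with identical sequences; optionally drop one
    residue from the template to emulate an internal deletion."""
    seq = ["MET", "LYS", "ARG", "SER", "THR", "GLU"]
    target = model_from_atoms(
        [("A", i + 1, rn, "CA", (float(i), 0.0, 0.5 * (i % 2))) for i, rn in enumerate(seq)]
    )
    template_entries = [
        ("B", i + 1, rn, "CA", (float(i), 0.0, 0.5 * (i % 2)))
        for i, rn in enumerate(seq)
        if template_missing is None or i + 1 != template_missing
    ]
    return target, model_from_atoms(template_entries)


class TestPairing:
    def test_identical_sequences_fully_paired(self):
        target, template = _protein_pair()
        pairing = pair_by_alignment(target, template, ("A", "B"))
        assert len(pairing) == 6
        assert pairing.identity == pytest.approx(1.0)
        assert [t.resnum for t, _ in pairing.pairs] == [1, 2, 3, 4, 5, 6]

    def test_internal_deletion_skips_exactly_that_position(self):
        target, template = _protein_pair(template_missing=3)
        pairing = pair_by_alignment(target, template, ("A", "B"))
        paired_targets = {t.resnum for t, _ in pairing.pairs}
        assert paired_targets == {1, 2, 4, 5, 6}

    def test_low_identity_template_refused(self):
        target = model_from_atoms(
            [("A", i + 1, rn, "CA", (float(i), 0, 0))
             for i, rn in enumerate(["LYS"] * 8)]
        )
        template = model_from_atoms(
            [("B", i + 1, rn, "CA", (float(i), 0, 0))
             for i, rn in enumerate(["TRP"] * 8)]
        )
        with pytest.raises(ValueError, match="identity"):
            pair_by_alignment(target, template, ("A", "B"))

    def test_dna_chain_rejected(self, toy_complex):
        model, _ = toy_complex
        with pytest.raises(ValueError, match="protein"):
            pair_by_alignment(model, model, ("A", "P"))


GRAFT_SPEC = ComplexSpec(
    planted=(
        PlantedContact("LYS", "salt_bridge", "phosphate", 2.8),
        PlantedContact("ARG", "salt_bridge", "phosphate", 2.8),
        PlantedContact("GLN", "hydrogen_bond", "base", 3.0),
        PlantedContact("TYR", "hydrogen_bond", "phosphate", 3.2),
        PlantedContact("THR", "hydrogen_bond", "sugar", 3.0),
    ),
    seed=13,
)


@pytest.fixture(scope="module")
def graft_complex():
    model, _ = generate_toy_complex(GRAFT_SPEC)
    return model


def _transformed_copy(model, seed=0):
    rng = np.random.default_rng(seed)
    R, t = rigid(rng)
    new = StructureModel()
    for cid, residues in model.chains.items():
        for key, atoms in residues.items():
            for a in atoms:
                new.add_atom(
                    key,
                    AtomRecord(a.name, a.element, tuple(R @ np.asarray(a.coords) + t),
                               a.altloc, a.occupancy),
                )
    return new


class TestGrafting:
    @pytest.mark.parametrize("resnum", [10, 20, 30, 40, 50])
    def test_strip_then_graft_identity(self, graft_complex, resnum):
        stripped = strip_sidechain(graft_complex, "P", resnum)
        key = stripped.find_residue("P", resnum)
        completed, rmsd = graft_sidechain(stripped, graft_complex, (key, key))
        assert rmsd <= 1e-9
        assert max_deviation(completed, graft_complex, "P", resnum) <= 1e-6

    @pytest.mark.parametrize("resnum", [10, 30, 50])
    def test_local_fit_cancels_global_template_transform(self, graft_complex, resnum):
        stripped = strip_sidechain(graft_complex, "P", resnum)
        template = _transformed_copy(graft_complex, seed=resnum)
        key = stripped.find_residue("P", resnum)
        completed, _ = graft_sidechain(stripped, template, (key, key))
        assert max_deviation(completed, graft_complex, "P", resnum) <= 1e-6

    def test_grafting_never_moves_existing_atoms(self, graft_complex):
        stripped = strip_sidechain(graft_complex, "P", 20)
        key = stripped.find_residue("P", 20)
        completed, _ = graft_sidechain(stripped, graft_complex, (key, key))
        for k in stripped.residues():
            before = {a.name: a.coords for a in stripped.atoms(k)}
            after = {a.name: a.coords for a in completed.atoms(k)}
            for name, xyz in before.items():
                assert after[name] == xyz

    def test_resname_mismatch_refused_by_default(self, graft_complex):
        stripped = strip_sidechain(graft_complex, "P", 10)  # LYS
        k_target = stripped.find_residue("P", 10)
        k_template = graft_complex.find_residue("P", 20)  # ARG
        with pytest.raises(ValueError, match="mismatch"):
            graft_sidechain(stripped, graft_complex, (k_target, k_template))

    def test_complete_model_empty_list_is_identity(self, graft_complex):
        model, report = complete_model(graft_complex, graft_complex, [])
        assert report == []
        assert model.n_atoms() == graft_complex.n_atoms()

    def test_complete_model_grafts_all_and_reports(self, graft_complex):
        resnums = [10, 20, 30, 40, 50]
        stripped = graft_complex
        for rn in resnums:
            stripped = strip_sidechain(stripped, "P", rn)
        missing = missing_sidechain_residues(stripped)
        assert sorted(k.resnum for k in missing) == resnums
        completed, report = complete_model(stripped, graft_complex, missing)
        assert [e["status"] for e in report] == ["ok"] * 5
        assert missing_sidechain_residues(completed) == []
        for rn in resnums:
            assert max_deviation(completed, graft_complex, "P", rn) <= 1e-6

    def test_complete_model_records_failures_but_continues(self, graft_complex):
        from pouscan.structure import ResidueKey

        stripped = strip_sidechain(graft_complex, "P", 30)
        missing = missing_sidechain_residues(stripped)
        ghost = ResidueKey(chain_id="P", resnum=999, resname="LYS")
        completed, report = complete_model(stripped, graft_complex, [ghost] + missing)
        by_res = {e["resnum"]: e["status"] for e in report}
        assert by_res[999] == "failed"
        assert by_res[30] == "ok"
        assert missing_sidechain_residues(completed) == []

    def test_grafted_residues_tracked_in_metadata(self, graft_complex):
        stripped = strip_sidechain(graft_complex, "P", 40)
        key = stripped.find_residue("P", 40)
        completed, _ = graft_sidechain(stripped, graft_complex, (key, key))
        assert key in completed.metadata["grafted_residues"]
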