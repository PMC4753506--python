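import math
from fractions import Fraction

import numpy as np
import pytest

from pouscan.phenotype import (
    PhenotypeRecord,
    ReporterRecord,
    StabilityRecord,
    classify_defective,
    estimate_half_life,
    integrate,
    normalize_band_intensity,
    normalize_colonies,
    normalize_reporter,
    permutation_pvalue,
    read_phenotype_tsv,
    write_phenotype_tsv,
)
from pouscan.synthetic import PhenotypeSpec, generate_phenotype_table


def rec(mutant, counts, positions=()):
    return PhenotypeRecord(mutant=mutant, positions=tuple(positions), counts=tuple(counts))


class TestNormalizeColonies:
    def test_fractions(self):
        records = normalize_colonies(
            [rec("WT", (100, 100, 100)), rec("Y327A", (45, 45, 45), (327,)),
             rec("dead", (0, 0, 0), (5,))]
        )
        by = {r.mutant: r.fraction_of_wt for r in records}
        assert by["WT"] == pytest.approx(1.0)
        assert by["Y327A"] == pytest.approx(0.45)
        assert by["dead"] == 0.0

    def test_zero_wt_rejected(self):
        with pytest.raises(ValueError, match="wild-type"):
            normalize_colonies([rec("WT", (0, 0)), rec("m", (5, 5), (1,))])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            rec("m", (5, -1), (1,))


class TestPermutationTest:
    def test_hand_enumerated_case(self):
        # pooled {1,2,10,11}, nx=2: 6 assignments; only {1,2} gives a mean
        # difference as low as the observed one
        assert permutation_pvalue((1, 2), (10, 11), "less") == pytest.approx(1 / 6)

    def test_two_sided_doubles_extreme_tail(self):
        p = permutation_pvalue((1, 2), (10, 11), "two-sided")
        assert p == pytest.approx(2 / 6)

    def test_identical_groups_not_significant(self):
        assert permutation_pvalue((5, 5, 5), (5, 5, 5), "less") == 1.0

    def test_three_vs_three_minimum(self):
        # fully separated 3v3: p = 1/C(6,3)
        assert permutation_pvalue((1, 2, 3), (10, 11, 12), "less") == pytest.approx(
            Fraction(1, 20)
        )


class TestClassifyDefective:
    def test_zero_fraction_is_defective(self):
        records = classify_defective(
            [rec("WT", (100, 110, 90)), rec("m", (0, 0, 0), (1,))]
        )
        assert {r.mutant: r.defect_class for r in records}["m"] == "defective"

    def test_nonsignificant_full_activity_is_normal(self):
        records = classify_defective(
            [rec("WT", (100, 110, 90)), rec("m", (102, 95, 108), (1,))]
        )
        assert {r.mutant: r.defect_class for r in records}["m"] == "normal"

    def test_significant_but_above_threshold_is_reduced(self):
        records = classify_defective(
            [rec("WT", (100, 101, 102)), rec("m", (70, 71, 72), (1,))]
        )
        assert {r.mutant: r.defect_class for r in records}["m"] == "reduced"

    def test_single_replicate_falls_back_to_threshold(self):
        records = classify_defective([rec("WT", (100,)), rec("m", (10,), (1,))])
        m = {r.mutant: r for r in records}["m"]
        assert m.defect_class == "defective"
        assert m.threshold_only

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_monotonicity(self, seed):
        records, _ = generate_phenotype_table(PhenotypeSpec(n_mutants=30, n_defective=10,
                                                            seed=seed))
        low = {r.mutant for r in classify_defective(records, threshold=0.3)
               if r.defect_class == "defective"}
        high = {r.mutant for r in classify_defective(records, threshold=0.7)
                if r.defect_class == "defective"}
        assert low <= high


class TestReporter:
    def test_worked_example(self):
        out = normalize_reporter(
            ReporterRecord("Oct4", "6xCR4", firefly=(1000,), renilla=(500,)),
            ReporterRecord("mock", "6xCR4", firefly=(100,), renilla=(200,)),
        )
        assert out.relative_activity == pytest.approx(4.0)

    def test_construct_equal_to_mock_is_unity(self):
        mock = ReporterRecord("mock", "5xW", firefly=(300,), renilla=(150,))
        assert normalize_reporter(mock, mock).relative_activity == pytest.approx(1.0)

    def test_zero_renilla_rejected(self):
        with pytest.raises(ValueError, match="renilla"):
            ReporterRecord("x", "5xW", firefly=(10,), renilla=(0,))

    def test_planted_fold_recovered_within_ten_percent(self):
        rng = np.random.default_rng(0)
        fold, n = 6.0, 4
        mock_ratio = 0.5
        firefly = fold * mock_ratio * 200 * rng.lognormal(0, 0.05, n)
        renilla = 200 * rng.lognormal(0, 0.05, n)
        out = normalize_reporter(
            ReporterRecord("x", "6xCR4", tuple(firefly), tuple(renilla)),
            ReporterRecord("mock", "6xCR4", (100.0,), (200.0,)),
        )
        assert out.relative_activity == pytest.approx(fold, rel=0.10)


class TestStability:
    def test_constant_ratio_normalises_to_one(self):
        out = normalize_band_intensity(
            StabilityRecord("WT", (0, 2, 4, 6), (50, 40, 30, 20), (100, 80, 60, 40))
        )
        assert out.relative_level == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_halving_series(self):
        out = normalize_band_intensity(
            StabilityRecord("S186A", (0, 2, 4, 6), (80, 40, 20, 10), (10, 10, 10, 10))
        )
        assert out.relative_level == pytest.approx((1.0, 0.5, 0.25, 0.125))

    def test_zero_gfp_rejected(self):
        with pytest.raises(ValueError, match="GFP"):
            normalize_band_intensity(
                StabilityRecord("x", (0, 2), (10, 10), (10, 0))
            )

    def test_ratios_match_hand_computation_with_noise(self):
        oct4 = (81.0, 44.0, 19.0, 11.0)
        gfp = (9.0, 11.0, 10.0, 9.5)
        out = normalize_band_intensity(StabilityRecord("x", (0, 2, 4, 6), oct4, gfp))
        expected = [o / g for o, g in zip(oct4, gfp)]
        expected = tuple(v / expected[0] for v in expected)
        assert out.relative_level == pytest.approx(expected)


class TestHalfLife:
    def test_exact_geometric_decay(self):
        assert estimate_half_life((0, 2, 4), (1.0, 0.5, 0.25)) == pytest.approx(2.0)

    def test_flat_series_undefined(self):
        assert estimate_half_life((0, 2, 4), (1.0, 1.0, 1.0)) is None

    def test_growing_series_undefined(self):
        assert estimate_half_life((0, 2, 4), (1.0, 1.4, 2.1)) is None

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            estimate_half_life((0, 2, 4), (1.0, 0.5, 0.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_recovery_within_fifteen_percent(self, seed):
        rng = np.random.default_rng(seed)
        true_t12 = 3.0
        t = np.array([0.0, 2.0, 4.0, 6.0])
        levels = np.exp(-math.log(2) / true_t12 * t) * rng.lognormal(0, 0.05, len(t))
        levels = levels / levels[0]
        est = estimate_half_life(tuple(t), tuple(levels))
        assert est == pytest.approx(true_t12, rel=0.15)


def fisher_two_sided_enumeration(a, b, c, d) -> float:
    """Integer-exact two-sided Fisher p by enumerating the hypergeometric
    support at fixed margins (sums all tables no more probable than the
    observed one)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weight = lambda k: math.comb(r1, k) * math.comb(n - r1, c1 - k)
    observed = weight(a)
    total = math.comb(n, c1)
    tail = sum(weight(k) for k in range(lo, hi + 1) if weight(k) <= observed)
    return tail / total


class TestIntegration:
    def _classified(self):
        records = [
            rec("WT", (100, 100, 100)),
            rec("K150A", (1, 0, 2), (150,)),
            rec("S186A", (5, 4, 6), (186,)),
            rec("Y327A", (45, 44, 46), (327,)),
            rec("S10A", (100, 99, 101), (10,)),
        ]
        return classify_defective(records)

    def test_empty_phenotypes_give_empty_table(self):
        table = integrate([])
        assert table.table.empty
        assert math.isnan(table.fisher_p)

    def test_marginals_match_inputs(self):
        table = integrate(self._classified(), interface_positions={150, 186})
        assert int(table.counts_2x2.sum()) == 4  # WT carries no position
        defective = table.table["defect_class"] == "defective"
        assert table.counts_2x2[0].sum() == int(defective.sum())

    def test_non_pou_defective_isolated(self):
        table = integrate(self._classified(), interface_positions={150, 186},
                          pou_span=(131, 289))
        df = table.table
        outside = df[(df["defect_class"] == "defective") & (~df["in_pou"])]
        assert list(outside["position"]) == [327]

    def test_fisher_p_matches_enumeration_oracle(self):
        table = integrate(self._classified(), interface_positions={150, 186})
        (a, b), (c, d) = table.counts_2x2
        assert table.fisher_p == pytest.approx(
            fisher_two_sided_enumeration(a, b, c, d), rel=1e-9
        )

    def test_position_collision_rejected(self):
        records = classify_defective(
            [rec("WT", (100, 100, 100)), rec("K5A", (0, 0, 0), (5,)),
             rec("K5R", (50, 50, 50), (5,))]
        )
        with pytest.raises(ValueError, match="collision"):
            integrate(records)

    def test_multi_site_mutant_rows_flagged_shared(self):
        records = classify_defective(
            [rec("WT", (100, 100, 100)), rec("S229/230A", (0, 0, 0), (229, 230))]
        )
        table = integrate(records)
        df = table.table
        assert list(df["position"]) == [229, 230]
        assert df["shared_evidence"].all()
        assert (df["defect_class"] == "defective").all()

    def test_unclassified_records_rejected(self):
        with pytest.raises(ValueError, match="classified"):
            integrate([rec("m", (1, 2, 3), (5,))])


def test_tsv_roundtrip():
    records, _ = generate_phenotype_table(PhenotypeSpec(n_mutants=10, n_defective=3, seed=0))
    text = write_phenotype_tsv(records)
    back = read_phenotype_tsv(text)
    assert [(r.mutant, r.positions, r.counts) for r in back] == [
        (r.mutant, r.positions, r.counts) for r in records
    ]
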