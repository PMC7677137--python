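"""Reporting statistics: odds ratios, percent decreases, composition, tests."""

import numpy as np
import pandas as pd
import pytest

from hlamatch.stats import (
    donor_composition,
    donor_count_test,
    grouped_match_rates,
    odds_ratio,
    percent_decrease,
    round_half_away,
    sibling_match_prob,
    two_prop_ztest,
)


def _or_vectors(a, b, c, d):
    """outcome/group vectors realizing the 2x2 table (a,b,c,d)."""
    outcome = np.array([1] * a + [0] * b + [1] * c + [0] * d)
    group = np.array([1] * (a + b) + [0] * (c + d))
    return outcome, group


class TestOddsRatio:
    def test_symmetric_table_gives_unity(self):
        res = odds_ratio(*_or_vectors(10, 10, 10, 10))
        assert res.oddsratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_cross_product(self):
        res = odds_ratio(*_or_vectors(20, 10, 10, 20))
        assert res.oddsratio == pytest.approx(4.0)
        assert res.logistic_or == pytest.approx(4.0, abs=1e-6)

    def test_logistic_cross_check_on_random_tables(self, rng):
        for _ in range(50):
            cells = rng.integers(1, 40, size=4)
            res = odds_ratio(*_or_vectors(*cells))
            assert res.logistic_or == pytest.approx(res.oddsratio, abs=1e-6)

    def test_zero_cell_correction_flagged(self):
        res = odds_ratio(*_or_vectors(10, 0, 5, 5))
        assert res.corrected
        assert np.isfinite(res.oddsratio) and res.oddsratio > 0

    def test_reciprocal_under_group_swap(self, rng):
        outcome, group = _or_vectors(17, 8, 6, 21)
        a = odds_ratio(outcome, group)
        b = odds_ratio(outcome, 1 - group)
        assert a.oddsratio == pytest.approx(1.0 / b.oddsratio)

    def test_single_outcome_level_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(np.ones(10, int), np.array([0, 1] * 5))


class TestPercentDecrease:
    def test_equal_rates_give_zero(self):
        assert percent_decrease(rates=(0.5, 0.5)).rounded == 0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_decrease(rates=(0.0, 0.1))

    def test_matched_sizes_converges_when_rates_size_independent(self, rng):
        # both groups share the same underlying rate: the size-matched
        # estimate approaches the plain one as replicates accumulate
        big = (rng.random(2000) < 0.6).astype(float)
        small = (rng.random(200) < 0.6).astype(float)
        plain = percent_decrease(big, small)
        matched = percent_decrease(big, small, matched_sizes=True,
                                   subsample_reps=500, rng=1)
        assert matched.rate_ref == pytest.approx(big.mean(), abs=0.02)
        assert abs(matched.raw - plain.raw) < 5.0

    def test_rounding_half_away(self):
        assert round_half_away(56.5) == 57
        assert round_half_away(-56.5) == -57
        assert round_half_away(82.94, 1) == 82.9


class TestDonorComposition:
    def test_per_patient_frequencies(self):
        counts = pd.DataFrame({"Black": [2], "White": [2]}, index=["P1"])
        groups = pd.Series({"P1": "g"})
        comp = donor_composition(counts, groups)
        assert comp.loc["g", "Black"] == pytest.approx(0.5)

    def test_average_of_averages_not_pooled(self):
        # patient1: 1 Black donor; patient2: 2 White donors ->
        # group mean (0.5, 0.5), not the pooled (1/3, 2/3)
        counts = pd.DataFrame({"Black": [1, 0], "White": [0, 2]},
                              index=["P1", "P2"])
        groups = pd.Series({"P1": "g", "P2": "g"})
        comp = donor_composition(counts, groups)
        assert comp.loc["g", "Black"] == pytest.approx(0.5)
        assert comp.loc["g", "White"] == pytest.approx(0.5)

    def test_unmatched_patients_excluded_and_rows_normalized(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 5, size=(30, 3)), columns=["Black", "Mixed", "White"],
            index=[f"P{i}" for i in range(30)],
        )
        counts.iloc[0] = 0  # no matches: must not contribute
        groups = pd.Series(rng.choice(["g1", "g2"], 30), index=counts.index)
        comp = donor_composition(counts, groups)
        assert np.allclose(comp.sum(axis=1), 1.0)


class TestGroupedRates:
    def test_rates_per_group(self):
        table = pd.DataFrame({"patient_id": [f"P{i}" for i in range(20)],
                              "n_matches": [1] * 10 + [0] * 10})
        assign = pd.Series(["a"] * 10 + ["b"] * 10,
                           index=[f"P{i}" for i in range(20)])
        gr = grouped_match_rates(table, assign, "test")
        assert gr.rate("a") == 1.0 and gr.rate("b") == 0.0

    def test_missing_assignment_rejected(self):
        table = pd.DataFrame({"patient_id": ["P1"], "n_matches": [1]})
        with pytest.raises(ValueError):
            grouped_match_rates(table, pd.Series(dtype=object), "test")


class TestDonorCountTest:
    def test_identical_samples_not_significant(self, rng):
        x = rng.integers(1, 50, size=100).astype(float)
        _, p = donor_count_test(x, x.copy())
        assert p > 0.9

    def test_disjoint_shifted_samples_significant(self):
        a = np.arange(100, 120, dtype=float)
        b = np.arange(1, 21, dtype=float)
        _, p = donor_count_test(a, b)
        assert p < 0.001

    def test_u_statistic_identity(self, rng):
        a = rng.integers(1, 100, size=25).astype(float)
        b = rng.integers(1, 100, size=30).astype(float)
        u_ab, _ = donor_count_test(a, b)
        u_ba, _ = donor_count_test(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))


class TestTwoPropZ:
    def test_equal_proportions_give_zero(self):
        z, p = two_prop_ztest(0.3, 100, 0.3, 200)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric_under_swap(self):
        z1, p1 = two_prop_ztest(0.2, 150, 0.35, 400)
        z2, p2 = two_prop_ztest(0.35, 400, 0.2, 150)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)


class TestSiblingMatch:
    def test_no_siblings_no_chance(self):
        assert sibling_match_prob(0) == 0.0

    def test_closed_form(self):
        assert sibling_match_prob(2) == pytest.approx(1 - 0.75**2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sibling_match_prob(-1)
        with pytest.raises(TypeError):
            sibling_match_prob(1.5)
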