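"""POR/Woolf, Fisher exact, chi-square, t-test, and logistic per-unit OR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyrisk.stats import (
    ContingencyTable2x2,
    SeparationError,
    chi_square,
    fisher_exact,
    logistic_or_per_unit,
    prevalence_odds_ratio,
    t_test,
)


def fisher_enumeration(a, b, c, d):
    """Independent oracle: full hypergeometric enumeration at fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def p_of(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )
    p_obs = p_of(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(p_of(x) for x in range(lo, hi + 1) if p_of(x) <= p_obs * (1 + 1e-9))


class TestPOR:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            # published cohort rows whose printed counts are internally consistent
            ((236, 143, 71, 22), (0.51, 0.30, 0.86)),
            ((301, 172, 176, 62), (0.62, 0.44, 0.87)),
            ((132, 112, 71, 22), (0.37, 0.21, 0.63)),
        ],
    )
    def test_reproduces_published_rows_to_two_decimals(self, cells, expected):
        res = prevalence_odds_ratio(ContingencyTable2x2(*cells))
        assert res.rounded(2) == expected

    def test_symmetric_table_gives_unity(self):
        res = prevalence_odds_ratio(ContingencyTable2x2(5, 5, 5, 5))
        assert res.por == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    @given(st.tuples(*[st.integers(1, 200)] * 4))
    @settings(derandomize=True, max_examples=100)
    def test_transposition_inverts_por_and_swaps_ci(self, cells):
        t = ContingencyTable2x2(*cells)
        r1 = prevalence_odds_ratio(t)
        r2 = prevalence_odds_ratio(t.transpose_exposure())
        assert r2.por == pytest.approx(1 / r1.por)
        assert r2.ci_low == pytest.approx(1 / r1.ci_high)
        assert r2.ci_high == pytest.approx(1 / r1.ci_low)

    def test_zero_cell_haldane_correction_tagged(self):
        res = prevalence_odds_ratio(ContingencyTable2x2(10, 0, 5, 5))
        assert "haldane" in res.method
        assert res.por == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))

    def test_empty_margin_undefined(self):
        with pytest.raises(ValueError, match="margin"):
            prevalence_odds_ratio(ContingencyTable2x2(0, 0, 5, 5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)


class TestFisher:
    def test_extreme_table_matches_direct_enumeration(self):
        # 2 of the C(20,10) equally-margined tables are as extreme
        p = fisher_exact(ContingencyTable2x2(10, 0, 0, 10))
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_balanced_table_p_one(self):
        assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    @given(st.tuples(*[st.integers(0, 10)] * 4).filter(lambda t: sum(t) > 0
                                                       and min(t[0]+t[1], t[2]+t[3]) > 0))
    @settings(derandomize=True, max_examples=150)
    def test_matches_enumeration_oracle_small_tables(self, cells):
        t = ContingencyTable2x2(*cells)
        assert fisher_exact(t) == pytest.approx(
            fisher_enumeration(*cells), rel=1e-6, abs=1e-12
        )

    def test_monotone_under_proportional_scaling(self):
        # fixed odds ratio != 1: doubling all counts strengthens the evidence
        p1 = fisher_exact(ContingencyTable2x2(8, 2, 2, 8))
        p2 = fisher_exact(ContingencyTable2x2(16, 4, 4, 16))
        assert 0 < p2 < p1 <= 1


class TestChiSquare:
    def test_proportional_table_statistic_zero(self):
        stat, p, df = chi_square([[10, 20], [20, 40]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0) and df == 1

    def test_hand_computed_two_by_two(self):
        # all expected counts 15; sum of (O-E)^2/E = 4 * 25/15
        stat, p, df = chi_square([[20, 10], [10, 20]])
        assert stat == pytest.approx(100 / 15)
        assert df == 1

    def test_three_by_two_matches_textbook_formula(self):
        obs = np.array([[12, 8], [10, 15], [4, 11]])
        stat, p, df = chi_square(obs)
        row, col, total = obs.sum(1), obs.sum(0), obs.sum()
        expected = np.outer(row, col) / total
        assert stat == pytest.approx(((obs - expected) ** 2 / expected).sum())
        assert df == 2

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 5]])


class TestTTest:
    def test_identical_samples_p_one(self):
        x = [3.0, 3.0, 3.0]
        assert t_test(x, list(x)) == pytest.approx(1.0)

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        assert t_test(x, x + 50) < 1e-6

    def test_null_calibration(self):
        """Monte-Carlo: rejection rate at alpha=.05 within 0.05 +/- 0.02."""
        rng = np.random.default_rng(42)
        rejections = sum(
            t_test(rng.normal(0, 1, 30), rng.normal(0, 1, 30)) < 0.05
            for _ in range(1000)
        )
        assert abs(rejections / 1000 - 0.05) <= 0.02


class TestLogistic:
    def test_null_covers_one(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(5, 500)
        y = rng.integers(0, 2, 500)
        res = logistic_or_per_unit(x, y)
        assert res.ci_low < 1.0 < res.ci_high

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            logistic_or_per_unit([3, 3, 3, 3], [0, 1, 0, 1])

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_or_per_unit([1, 2, 3, 4], [1, 1, 1, 1])

    def test_complete_separation_flagged(self):
        x = np.arange(20)
        y = (x >= 10).astype(int)
        with pytest.raises(SeparationError):
            logistic_or_per_unit(x, y)

    def test_slope_bias_shrinks_with_n(self):
        """Parameter recovery improves with sample size on simulated data."""
        true_or = 1.39
        def mean_abs_bias(n, reps, seed):
            rng = np.random.default_rng(seed)
            biases = []
            for _ in range(reps):
                x = rng.poisson(6, n)
                p = 1 / (1 + np.exp(-(-2.0 + math.log(true_or) * x)))
                y = (rng.random(n) < p).astype(int)
                biases.append(abs(logistic_or_per_unit(x, y).por - true_or))
            return np.mean(biases)
        assert mean_abs_bias(2000, 15, 0) < mean_abs_bias(120, 15, 1)
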