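"""Statistical primitives against hand-formula and enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from aneuexpr.stats import (
    bh_fdr,
    chisq_contingency,
    chisq_gof,
    welch_t,
    wilcoxon_signed_rank,
)


class TestChisqGof:
    @pytest.mark.parametrize(
        "counts, printed_p",
        [
            ((1561, 1770), 2.93e-4),
            ((3433, 3343), 0.27),
            ((2586, 2852), 3.10e-4),
            ((49, 47), 0.84),
        ],
    )
    def test_directional_bias_values(self, counts, printed_p):
        """Up/down bias p-values match the published two-decimal /
        two-significant-figure values for the same counts."""
        res = chisq_gof(counts)
        assert float(f"{res.p:.2e}") == pytest.approx(printed_p, rel=0.02)

    def test_extreme_bias_below_reporting_floor(self):
        res = chisq_gof((950, 1756))
        assert res.statistic == pytest.approx(240.07, abs=0.01)
        assert res.p <= 2.20e-16

    def test_perfect_fit(self):
        res = chisq_gof((123, 123))
        assert res.statistic == 0.0
        assert res.p == 1.0

    @given(
        a=st.integers(min_value=1, max_value=5000),
        b=st.integers(min_value=1, max_value=5000),
    )
    def test_two_category_closed_form(self, a, b):
        """For k=2 uniform GOF, p = 2*Phi(-sqrt(chi2)) exactly."""
        res = chisq_gof((a, b))
        closed = 2.0 * sps.norm.sf(np.sqrt(res.statistic))
        assert res.p == pytest.approx(closed, rel=1e-12, abs=1e-300)

    def test_nonuniform_expectation(self):
        # observed matching a 3:1 null exactly
        res = chisq_gof((75, 25), expected_proportions=(0.75, 0.25))
        assert res.statistic == 0.0

    @pytest.mark.parametrize(
        "bad, kwargs",
        [
            ((0, 0), {}),
            ((-1, 5), {}),
            ((3, 4), {"expected_proportions": (1.0, 0.0)}),
            ((3, 4), {"expected_proportions": (0.6, 0.6)}),
        ],
    )
    def test_invalid_inputs(self, bad, kwargs):
        with pytest.raises(ValueError):
            chisq_gof(bad, **kwargs)


class TestChisqContingency:
    def test_independence(self):
        res = chisq_contingency([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_hand_formula_2x2(self):
        """Pearson statistic on a 2x2 computed by the direct
        sum((O-E)^2/E) formula, uncorrected and with Yates."""
        tab = np.array([[32, 40], [15, 33]], dtype=float)
        expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        stat_hand = (((tab - expected) ** 2) / expected).sum()
        res = chisq_contingency(tab, correction=False)
        assert res.statistic == pytest.approx(stat_hand, rel=1e-12)
        assert res.p == pytest.approx(sps.chi2.sf(stat_hand, 1), rel=1e-12)
        stat_yates = (((np.abs(tab - expected) - 0.5) ** 2) / expected).sum()
        res_y = chisq_contingency(tab, correction=True)
        assert res_y.statistic == pytest.approx(stat_yates, rel=1e-12)

    def test_doubling_cells_doubles_statistic(self):
        tab = np.array([[12, 30], [25, 9]], dtype=float)
        s1 = chisq_contingency(tab).statistic
        s2 = chisq_contingency(2 * tab).statistic
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_contingency([[0, 0], [5, 3]])


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_all_ones_capped(self):
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_step_up_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @staticmethod
    def _step_up(p):
        """Direct evaluation of q_(i) = min_{j>=i} p_(j) * n / j."""
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        q_sorted = p[order] * n / np.arange(1, n + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q = np.empty(n)
        q[order] = np.minimum(q_sorted, 1.0)
        return q

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    def test_matches_direct_step_up(self, pvals):
        assert np.allclose(bh_fdr(pvals), self._step_up(pvals), atol=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30)
    )
    def test_monotone_along_sorted_p(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_equal_variance_df(self):
        """With equal sizes and equal sample variances the Satterthwaite
        df collapses to the pooled 2n - 2."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([10.0, 11.0, 12.0, 13.0])
        assert welch_t(x, y).df == pytest.approx(2 * 4 - 2)

    def test_hand_formula_oracle(self):
        # frozen from the explicit Welch/Satterthwaite formulas:
        # x=(100,102,98), y=(50,51,49): vx=4, vy=1, t=50/sqrt(5/3),
        # df=(5/3)^2 / ((4/3)^2/2 + (1/3)^2/2)
        res = welch_t([100.0, 102.0, 98.0], [50.0, 51.0, 49.0])
        assert res.statistic == pytest.approx(38.72983346207417, rel=1e-10)
        assert res.df == pytest.approx(2.9411764705882346, rel=1e-10)
        assert res.p == pytest.approx(4.453287504609015e-05, rel=1e-9)

    def test_degenerate_zero_variance(self):
        res = welch_t([5.0, 5.0], [7.0, 7.0])
        assert res.degenerate
        assert res.p == 0.0
        res_eq = welch_t([5.0, 5.0], [5.0, 5.0])
        assert res_eq.degenerate and res_eq.p == 1.0

    def test_requires_two_observations(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])


def _enumeration_p(diffs):
    """Independent oracle: exact two-sided signed-rank p by brute-force
    enumeration of all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.array(ws)
    n = len(ws)
    cdf = (ws <= w_obs + 1e-9).sum() / n
    sf = (ws >= w_obs - 1e-9).sum() / n
    return min(1.0, 2.0 * min(cdf, sf))


class TestWilcoxonSignedRank:
    def test_perfect_symmetry(self):
        assert wilcoxon_signed_rank([1.0, -1.0]).p == 1.0

    def test_all_zero_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.degenerate and res.p == 1.0

    @pytest.mark.parametrize(
        "diffs",
        [
            [3.0, -1.2, 0.8, 2.5, -0.3, 1.9],
            [1.0, 1.0, -2.0, 3.0, -3.0, 0.5],  # ties in |d|
            [0.4, 0.9, 1.4, 2.2, -0.1, -2.9, 3.3, 1.1],
            [-1.0, -2.0, -3.0, -4.0],
        ],
    )
    def test_exact_equals_enumeration(self, diffs):
        assert wilcoxon_signed_rank(diffs).p == pytest.approx(
            _enumeration_p(diffs), abs=1e-12
        )

    def test_exact_close_to_normal_approximation_at_n25(self, rng):
        """At the exact/approximate switch point the two paths agree to
        |dp| <= 0.01 on random vectors."""
        worst = 0.0
        for _ in range(100):
            d = rng.normal(0.3, 1.0, size=25)
            d = d[d != 0]
            p_exact = wilcoxon_signed_rank(d, exact_max_n=25).p
            p_approx = wilcoxon_signed_rank(d, exact_max_n=0).p
            worst = max(worst, abs(p_exact - p_approx))
        assert worst <= 0.01

    def test_empty_after_zero_removal_needs_input(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([])
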