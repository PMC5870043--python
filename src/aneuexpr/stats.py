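"""Statistical primitives shared by every analysis stage.

The directional bias tests throughout the pipeline are uncorrected
chi-square goodness-of-fit tests on up/down counts; fold-change testing
uses Welch's t; per-chromosome expression shifts are supported by the
Wilcoxon signed-rank test; multiple testing is controlled with
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "chisq_gof",
    "chisq_contingency",
    "bh_fdr",
    "welch_t",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``df`` is NaN for tests without a meaningful degrees-of-freedom
    notion (e.g. the exact signed-rank path).  ``degenerate`` marks
    inputs on which the test statistic is undefined (all-zero
    differences, zero variance on both sides) and the p-value is set by
    the documented convention instead of a distributional computation.
    """

    statistic: float
    df: float
    p: float
    method: str
    corrected: bool = False
    degenerate: bool = False


def chisq_gof(observed, expected_proportions=None, correction: bool = False) -> TestResult:
    """Chi-square goodness-of-fit test on a vector of counts.

    Parameters
    ----------
    observed
        Non-negative counts, one per category.
    expected_proportions
        Null proportions summing to 1; uniform when omitted.  For two
        categories with uniform expectation this is the directional
        bias test used on up/down DEG counts.
    correction
        Apply the Yates continuity correction (|O-E| reduced by 0.5).
        The pipeline's bias tests never use it.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed must be a 1-D vector with >= 2 categories")
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    if expected_proportions is None:
        props = np.full(obs.size, 1.0 / obs.size)
    else:
        props = np.asarray(expected_proportions, dtype=float)
        if props.shape != obs.shape:
            raise ValueError("expected_proportions shape mismatch")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("expected_proportions must sum to 1")
    expected = total * props
    if np.any(expected == 0):
        raise ValueError("expected count of zero in at least one category")
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    df = obs.size - 1
    p = float(sps.chi2.sf(stat, df))
    return TestResult(stat, float(df), p, "chisq_gof", corrected=correction)


def chisq_contingency(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a contingency table."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, df, _ = sps.chi2_contingency(tab, correction=correction)
    return TestResult(float(stat), float(df), float(p), "chisq_contingency", corrected=correction)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Returns q in the input order, capped at 1.  Implemented via
    statsmodels' ``fdr_bh``; equivalent to
    q_(i) = min_{j >= i} p_(j) * n / j on the sorted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t(x, y) -> TestResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom.

    Zero variance in both samples leaves the statistic undefined; by
    contract the result is then flagged degenerate with p = 1 for equal
    means and p = 0 otherwise (classification proceeds by sign).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires >= 2 observations per sample")
    # constant samples, not variance == 0: var of identical values can
    # round to a nonzero ulp-scale number after transforms
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        equal = x.mean() == y.mean()
        stat = 0.0 if equal else np.sign(x.mean() - y.mean()) * np.inf
        return TestResult(float(stat), float("nan"), 1.0 if equal else 0.0,
                          "welch_t", degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), "welch_t")


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for the signed-rank statistic via dynamic
    programming over the 2^n equiprobable sign assignments.

    Ranks may be tied (average ranks); doubling makes them integers so
    the distribution is a polynomial product, equivalent to full
    enumeration but O(n * sum(ranks)).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dp = np.zeros(total + 1, dtype=float)
    dp[0] = 1.0
    for r in r2:
        new = dp.copy()
        new[r:] += dp[: total + 1 - r]
        dp = new
    dp /= dp.sum()
    w2 = int(np.rint(2 * w_plus))
    cdf = dp[: w2 + 1].sum()
    sf = dp[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(diffs, exact_max_n: int = 25) -> TestResult:
    """Wilcoxon signed-rank test of symmetry of ``diffs`` about zero.

    Zero differences are dropped first.  Up to ``exact_max_n`` non-zero
    differences the exact null distribution is used (correct under
    ties, since the conditional distribution given the observed ranks
    is enumerated); above that, the normal approximation with the
    standard tie correction and a 0.5 continuity correction.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one difference")
    d = d[d != 0]
    if d.size == 0:
        return TestResult(0.0, float("nan"), 1.0, "wilcoxon_signed_rank", degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= exact_max_n:
        p = _signed_rank_exact_p(w_plus, ranks)
        return TestResult(w_plus, float("nan"), p, "wilcoxon_signed_rank_exact")
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    dev = w_plus - mean
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var) if var > 0 else 0.0
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(w_plus, float("nan"), p, "wilcoxon_signed_rank_normal")
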