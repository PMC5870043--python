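"""Differential expression at the twofold / q < 0.05 decision rule.

Genes with mean FPKM > 0 in at least one group are tested.  The fold
change is log2((mean_test + pc) / (mean_ref + pc)) with pseudocount
pc = 1, which bounds fold changes of near-zero genes; the p-value is a
Welch two-sample t on log2(FPKM + pc) replicate values, and q is the
Benjamini-Hochberg adjustment over all tested genes.  A gene is a DEG
iff |log2FC| >= log2(fc_threshold) and q < q_threshold.

The original study ran a negative-binomial DE package on raw counts;
this module deliberately substitutes a fully specified, replicate-
variance-based test with the same decision rule, because every
downstream statistic (bias tests, cis/trans partitions, overlaps)
consumes only the DEG calls, not the test internals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import group_samples
from .stats import TestResult, bh_fdr, chisq_gof

__all__ = ["call_degs", "summarize_comparison", "ComparisonSummary"]


@dataclass
class ComparisonSummary:
    """Up/down DEG counts of one comparison with the directional bias test."""

    comparison: str
    n_deg: int
    n_up: int
    n_down: int
    pct_up: float
    pct_down: float
    bias: TestResult | None

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "n_deg": self.n_deg,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "pct_up": self.pct_up,
            "pct_down": self.pct_down,
            "bias_chi2": self.bias.statistic if self.bias else None,
            "bias_p": self.bias.p if self.bias else None,
        }


def call_degs(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    test: str,
    reference: str,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    pseudocount: float = 1.0,
    center_log2fc: bool = True,
) -> pd.DataFrame:
    """Per-gene DE results for ``test`` vs ``reference``.

    Returns a DataFrame indexed by gene id with columns ``log2fc``,
    ``p``, ``q``, ``direction`` and ``is_deg``; genes unexpressed in
    both groups are excluded from testing and from the BH family.

    ``center_log2fc`` applies a median-of-ratios correction: FPKM is a
    relative abundance, so asymmetric expression changes shift the
    whole fold-change distribution away from zero (composition bias).
    Under the assumption that most genes are unchanged, the median
    log2 ratio over tested genes estimates that shift; it is removed
    by rescaling the two groups symmetrically (a size-factor
    normalisation on the FPKM scale) before fold changes and tests.
    """
    test_cols = group_samples(samples, test)
    ref_cols = group_samples(samples, reference)
    if len(test_cols) < 2 or len(ref_cols) < 2:
        raise ValueError("call_degs requires >= 2 replicates per group")

    mt = expr[test_cols].mean(axis=1)
    mr = expr[ref_cols].mean(axis=1)
    tested = expr.index[(mt > 0) | (mr > 0)]

    raw = np.log2((mt[tested] + pseudocount) / (mr[tested] + pseudocount))
    shift = float(np.median(raw)) if center_log2fc else 0.0
    # split the correction between the groups so that swapping test and
    # reference negates every fold change exactly
    scale_t, scale_r = 2.0 ** (-shift / 2.0), 2.0 ** (shift / 2.0)
    mt, mr = mt * scale_t, mr * scale_r

    log2fc = np.log2((mt[tested] + pseudocount) / (mr[tested] + pseudocount))
    lt = np.log2(expr.loc[tested, test_cols] * scale_t + pseudocount).to_numpy()
    lr = np.log2(expr.loc[tested, ref_cols] * scale_r + pseudocount).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(lt, lr, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero variance on both sides leaves Welch undefined: p by the
    # degenerate convention (1 for equal means, 0 otherwise)
    bad = ~np.isfinite(pvals)
    if bad.any():
        pvals[bad] = np.where(lt[bad].mean(axis=1) == lr[bad].mean(axis=1), 1.0, 0.0)
    qvals = bh_fdr(pvals)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "q": qvals,
        },
        index=tested,
    )
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out["is_deg"] = (np.abs(out["log2fc"]) >= np.log2(fc_threshold)) & (
        out["q"] < q_threshold
    )
    out.index.name = "gene_id"
    return out


def summarize_comparison(name: str, deg_table: pd.DataFrame) -> ComparisonSummary:
    """Counts, percentages (2 decimals) and the up/down bias test.

    ``deg_table`` is the output of :func:`call_degs`; only rows with
    ``is_deg`` contribute.  With no DEGs the bias test is undefined and
    reported as None.
    """
    degs = deg_table[deg_table["is_deg"]] if "is_deg" in deg_table else deg_table
    n_up = int((degs["direction"] == "up").sum())
    n_down = int((degs["direction"] == "down").sum())
    n = n_up + n_down
    bias = chisq_gof([n_up, n_down]) if n > 0 else None
    return ComparisonSummary(
        comparison=name,
        n_deg=n,
        n_up=n_up,
        n_down=n_down,
        pct_up=round(100.0 * n_up / n, 2) if n else 0.0,
        pct_down=round(100.0 * n_down / n, 2) if n else 0.0,
        bias=bias,
    )
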