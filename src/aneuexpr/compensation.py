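"""Dosage-compensation classification of one-dose genes.

For every gene on a monosomic (copy-reduced) chromosome, the null
hypothesis is a pure dosage effect: the test-group mean equals half
the reference mean.  It is tested gene by gene with a Welch two-sample
t between the test replicates and the halved reference replicates, on
the log2(x + 1) scale by default (a linear-scale variant is a switch).

* null not rejected (p >= alpha)      -> non_compensated
* rejected, mean_test > mean_ref / 2  -> compensated
* rejected, mean_test < mean_ref / 2  -> anti_compensated
* mean reference FPKM <= 0.1          -> non_expressed (no test)

The cross-tabulation stratifies classified genes by their reference
expression bin (low / medium / high) and reports per-row chi-square
bias tests of the deviating classes (compensated + anti_compensated)
against non_compensated under equal expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import group_samples
from .quantify import assign_bins
from .stats import TestResult, chisq_gof, welch_t

__all__ = [
    "classify_one_dose_gene",
    "classify_chromosome",
    "compensation_crosstab",
    "CompensationCall",
    "CompensationCrossTab",
]

EXPRESSED_THRESHOLD = 0.1


@dataclass
class CompensationCall:
    gene_id: str
    comp_class: str
    mean_ref: float
    mean_test: float
    expected_test: float
    bin: str
    t_stat: float | None = None
    p: float | None = None
    degenerate: bool = False


def classify_one_dose_gene(
    ref_reps,
    test_reps,
    alpha: float = 0.05,
    gene_id: str = "",
    scale: str = "log2",
) -> CompensationCall:
    """Classify one gene on the reduced chromosome.

    ``ref_reps`` are the euploid (two-dose) FPKM replicates,
    ``test_reps`` the monosomic line's.  ``scale`` is "log2"
    (log2(x + 1) before testing) or "linear".
    """
    ref = np.asarray(ref_reps, dtype=float)
    test = np.asarray(test_reps, dtype=float)
    if ref.size < 2 or test.size < 2:
        raise ValueError("need >= 2 replicates on each side")
    if scale not in ("log2", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    mean_ref = float(ref.mean())
    mean_test = float(test.mean())
    expected = mean_ref / 2.0
    bin_label = str(assign_bins(pd.Series([mean_ref])).iloc[0])

    if mean_ref <= EXPRESSED_THRESHOLD:
        return CompensationCall(gene_id, "non_expressed", mean_ref, mean_test, expected, bin_label)

    half_ref = ref / 2.0
    if scale == "log2":
        res = welch_t(np.log2(test + 1.0), np.log2(half_ref + 1.0))
    else:
        res = welch_t(test, half_ref)
    if res.degenerate:
        # zero variance on both sides: classify by sign, no p-value
        if mean_test > expected:
            cls = "compensated"
        elif mean_test < expected:
            cls = "anti_compensated"
        else:
            cls = "non_compensated"
        return CompensationCall(
            gene_id, cls, mean_ref, mean_test, expected, bin_label, degenerate=True
        )
    if res.p < alpha:
        cls = "compensated" if mean_test > expected else "anti_compensated"
    else:
        cls = "non_compensated"
    return CompensationCall(
        gene_id, cls, mean_ref, mean_test, expected, bin_label, t_stat=res.statistic, p=res.p
    )


def classify_chromosome(
    expr: pd.DataFrame,
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    test: str,
    reference: str,
    chromosome: str,
    alpha: float = 0.05,
    scale: str = "log2",
) -> pd.DataFrame:
    """Compensation calls for every annotated gene on ``chromosome``."""
    test_cols = group_samples(samples, test)
    ref_cols = group_samples(samples, reference)
    on_chrom = genes.index[genes["chromosome"] == chromosome].intersection(expr.index)
    calls = [
        classify_one_dose_gene(
            expr.loc[g, ref_cols].to_numpy(),
            expr.loc[g, test_cols].to_numpy(),
            alpha=alpha,
            gene_id=g,
            scale=scale,
        )
        for g in on_chrom
    ]
    out = pd.DataFrame([vars(c) for c in calls])
    if len(out):
        out = out.set_index("gene_id")
    return out


@dataclass
class CompensationCrossTab:
    """Counts and row percentages of classes by expression bin."""

    counts: pd.DataFrame
    row_pct: pd.DataFrame
    row_bias: dict
    class_proportions: dict

    def to_dict(self) -> dict:
        return {
            "counts": {b: self.counts.loc[b].to_dict() for b in self.counts.index},
            "row_pct": {b: self.row_pct.loc[b].to_dict() for b in self.row_pct.index},
            "row_bias_p": {
                b: (r.p if isinstance(r, TestResult) else None)
                for b, r in self.row_bias.items()
            },
            "class_proportions": self.class_proportions,
        }


_CLASS_COLS = ["non_compensated", "compensated", "anti_compensated"]
_BIN_ROWS = ["low", "medium", "high"]


def compensation_crosstab(calls: pd.DataFrame) -> CompensationCrossTab:
    """Cross-tabulate compensation classes by reference expression bin.

    Rows are the low/medium/high bins; the per-row bias test is an
    uncorrected chi-square of (compensated + anti_compensated) vs
    non_compensated under equal expectation.  ``class_proportions``
    covers all classified genes, including non_expressed.
    """
    if calls is None or len(calls) == 0:
        empty = pd.DataFrame(0, index=_BIN_ROWS, columns=_CLASS_COLS)
        return CompensationCrossTab(empty, empty.astype(float), {}, {})
    counts = pd.DataFrame(0, index=_BIN_ROWS, columns=_CLASS_COLS)
    sub = calls[calls["comp_class"] != "non_expressed"]
    for b in _BIN_ROWS:
        for c in _CLASS_COLS:
            counts.loc[b, c] = int(((sub["bin"] == b) & (sub["comp_class"] == c)).sum())
    totals = counts.sum(axis=1)
    row_pct = counts.div(totals.replace(0, np.nan), axis=0).mul(100).round(2).fillna(0.0)
    row_bias = {}
    for b in _BIN_ROWS:
        deviating = int(counts.loc[b, "compensated"] + counts.loc[b, "anti_compensated"])
        non = int(counts.loc[b, "non_compensated"])
        row_bias[b] = chisq_gof([deviating, non]) if deviating + non > 0 else None
    n = len(calls)
    class_proportions = {
        cls: {
            "count": int((calls["comp_class"] == cls).sum()),
            "pct": round(100.0 * (calls["comp_class"] == cls).sum() / n, 2),
        }
        for cls in ["non_expressed"] + _CLASS_COLS
    }
    return CompensationCrossTab(counts, row_pct, row_bias, class_proportions)
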