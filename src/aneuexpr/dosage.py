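"""Chromosome dosage detection from expression shifts.

The copy number of each chromosome in a test group is inferred from
the per-gene log2 ratio of mean FPKM (test over euploid reference),
restricted to genes expressed (mean FPKM > 0) in both groups.  The
median ratio is matched to the nearest copy-number centre in log2
space: log2(c/2) for c in {1, 2, 3}, i.e. -1 / 0 / +0.585.  A Wilcoxon
signed-rank p-value of the ratios against zero is reported as
supporting evidence but plays no part in the call.

An alien chromosome absent from the reference (no expressed reference
genes) has no defined ratio; it is reported descriptively (number of
genes expressed in the test group and their mean FPKM) with call
"no_call", as is any chromosome with fewer than ``min_genes`` usable
genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import mean_group_expression
from .stats import wilcoxon_signed_rank

__all__ = ["chromosome_log2_ratios", "scan_dosage", "COPY_CENTERS"]

#: log2(copies / 2) for 1, 2 and 3 copies.
COPY_CENTERS = {1: -1.0, 2: 0.0, 3: np.log2(1.5)}


def chromosome_log2_ratios(
    expr: pd.DataFrame,
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    test: str,
    reference: str,
    chromosome: str,
) -> pd.Series:
    """Per-gene log2(mean_test / mean_reference) on one chromosome.

    Only genes with mean FPKM > 0 in both groups enter the ratio.
    """
    if chromosome not in set(genes["chromosome"]):
        raise KeyError(f"chromosome {chromosome!r} absent from annotation")
    on_chrom = genes.index[genes["chromosome"] == chromosome]
    on_chrom = on_chrom.intersection(expr.index)
    mt = mean_group_expression(expr.loc[on_chrom], samples, test)
    mr = mean_group_expression(expr.loc[on_chrom], samples, reference)
    usable = (mt > 0) & (mr > 0)
    return np.log2(mt[usable] / mr[usable])


def scan_dosage(
    expr: pd.DataFrame,
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    test: str,
    reference: str,
    min_genes: int = 10,
    center: bool = True,
) -> pd.DataFrame:
    """Copy-number call for every annotated chromosome.

    Returns one row per chromosome with the median log2 ratio, the
    supporting Wilcoxon p, the nearest-centre copy estimate and the
    call (reduced / normal / gained / no_call), plus descriptive
    columns for genes expressed in the test group only.

    With ``center`` (the default), and at least 5 callable
    chromosomes, each chromosome's median is taken relative to the
    consensus level — the median of the per-chromosome medians —
    before matching to a copy-number centre.  FPKM is a relative
    measure, so unbalanced expression changes shift every
    chromosome's ratio by a common offset; judging each box against
    the others is exactly how a chromosome-level box plot is read.
    The offset used is reported in ``consensus_log2``; the
    ``median_log2_ratio`` column stays uncentred.
    """
    rows = []
    for chrom in sorted(genes["chromosome"].unique()):
        on_chrom = genes.index[genes["chromosome"] == chrom].intersection(expr.index)
        mt = mean_group_expression(expr.loc[on_chrom], samples, test)
        mr = mean_group_expression(expr.loc[on_chrom], samples, reference)
        ratios = np.log2(mt[(mt > 0) & (mr > 0)] / mr[(mt > 0) & (mr > 0)])
        test_only = ((mt > 0) & (mr == 0)).sum()
        row = {
            "chromosome": chrom,
            "n_genes_used": int(len(ratios)),
            "n_test_only_expressed": int(test_only),
            "mean_test_fpkm": float(mt[mt > 0].mean()) if (mt > 0).any() else 0.0,
            "median_log2_ratio": np.nan,
            "wilcoxon_p": np.nan,
        }
        if len(ratios) >= min_genes:
            row["median_log2_ratio"] = float(ratios.median())
            row["wilcoxon_p"] = wilcoxon_signed_rank(ratios.to_numpy()).p
        rows.append(row)
    out = pd.DataFrame(rows)

    callable_ = out["median_log2_ratio"].notna()
    consensus = 0.0
    if center and callable_.sum() >= 5:
        consensus = float(out.loc[callable_, "median_log2_ratio"].median())
    out["consensus_log2"] = consensus

    copies_col, call_col = [], []
    for med in out["median_log2_ratio"]:
        if np.isnan(med):
            copies_col.append(pd.NA)
            call_col.append("no_call")
        else:
            m = med - consensus
            copies = min(COPY_CENTERS, key=lambda c: abs(m - COPY_CENTERS[c]))
            copies_col.append(copies)
            call_col.append({1: "reduced", 2: "normal", 3: "gained"}[copies])
    out["estimated_copies"] = pd.array(copies_col, dtype="Int64")
    out["call"] = call_col
    return out
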