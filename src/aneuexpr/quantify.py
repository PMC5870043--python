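"""Count-to-FPKM conversion and expression binning.

FPKM(g, s) = count(g, s) * 1e9 / (exonic_length(g) * total(s)), with
total(s) the column sum of the gene-level count matrix.  The expression
bins follow the reference-expression strata used for the compensation
cross-tabulation: low (0.1, 10], medium (10, 100], high (100, inf),
plus a sub_threshold bin (0, 0.1] and non_expressed for exact zero.
Upper edges are closed so the bins partition [0, inf).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import BIN_LABELS, group_samples

__all__ = ["compute_fpkm", "mean_group_expression", "assign_bins"]

#: default upper bounds of the sub_threshold / low / medium bins.
DEFAULT_BIN_EDGES = (0.1, 10.0, 100.0)


def compute_fpkm(counts: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Fragments-per-kilobase-per-million matrix from raw counts.

    Every gene in ``counts`` must carry an ``exonic_length`` in the
    annotation; a sample whose column sum is zero has no defined
    normalisation and raises an error naming it.
    """
    missing = counts.index.difference(genes.index)
    if len(missing):
        raise KeyError(f"genes missing from annotation: {missing[:5].tolist()}")
    lengths = genes.loc[counts.index, "exonic_length"].to_numpy(dtype=float)
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    zero = counts.columns[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total counts: {zero}")
    values = counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def mean_group_expression(expr: pd.DataFrame, samples: pd.DataFrame, group: str) -> pd.Series:
    """Arithmetic mean FPKM across a group's replicates."""
    cols = group_samples(samples, group)
    return expr[cols].mean(axis=1)


def assign_bins(mean_ref_fpkm: pd.Series, edges=DEFAULT_BIN_EDGES) -> pd.Series:
    """Map mean reference FPKM to expression bins.

    With the default edges: 0 -> non_expressed; (0, 0.1] ->
    sub_threshold; (0.1, 10] -> low; (10, 100] -> medium;
    (100, inf) -> high.  ``edges`` must be strictly increasing.
    """
    edges = tuple(float(e) for e in edges)
    if len(edges) != 3 or not (0 < edges[0] < edges[1] < edges[2]):
        raise ValueError("edges must be three strictly increasing positive bounds")
    x = pd.Series(mean_ref_fpkm, dtype=float)
    if (x < 0).any():
        raise ValueError("FPKM values must be non-negative")
    conditions = [x == 0]
    labels = ["non_expressed"]
    lower = 0.0
    for upper, label in zip(
        (*edges, np.inf), ("sub_threshold", "low", "medium", "high")
    ):
        conditions.append((x > lower) & (x <= upper))
        labels.append(label)
        lower = upper
    out = pd.Series(np.select(conditions, labels, default="__unassigned__"), index=x.index)
    if (out == "__unassigned__").any():
        raise ValueError("FPKM values must be finite")
    return out.astype(pd.CategoricalDtype(categories=list(BIN_LABELS), ordered=True))
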