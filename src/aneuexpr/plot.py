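"""Minimal plotting: the per-chromosome expression box plot used to
spot a dosage-shifted chromosome by eye."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .quantify import mean_group_expression  # noqa: E402

__all__ = ["chromosome_expression_boxplot"]


def chromosome_expression_boxplot(
    expr: pd.DataFrame,
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    groups: list,
    out_path,
    chromosomes: list | None = None,
):
    """Box plot of log2(mean FPKM) of expressed genes (FPKM > 0), one
    panel per group, one box per chromosome.  Returns the figure."""
    chroms = chromosomes or sorted(genes["chromosome"].unique())
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(max(6, 0.5 * len(chroms)), 2.5 * len(groups)), sharex=True
    )
    axes = np.atleast_1d(axes)
    for ax, group in zip(axes, groups):
        means = mean_group_expression(expr, samples, group)
        data = []
        for c in chroms:
            vals = means[genes.index[genes["chromosome"] == c].intersection(means.index)]
            vals = vals[vals > 0]
            data.append(np.log2(vals) if len(vals) else np.array([np.nan]))
        ax.boxplot(data, tick_labels=chroms, showfliers=False)
        ax.set_ylabel(f"{group}\nlog2(FPKM)")
        ax.axhline(0, color="grey", lw=0.5)
    axes[-1].set_xlabel("chromosome")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return fig
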