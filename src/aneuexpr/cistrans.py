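"""Cis/trans partitioning of DEGs and per-chromosome susceptibility.

A DEG is a cis-effect gene iff it lies on a chromosome whose copy
number differs between the two compared karyotypes (including an alien
chromosome's own genes); every other located DEG is a trans-effect
gene.  Directional bias within the trans set uses the uncorrected
chi-square goodness-of-fit test.  Susceptibility asks, for each
disomic chromosome, whether its share of DEGs departs from its share
of expressed genes (2x2 chi-square against all other disomic
chromosomes, BH-corrected across chromosomes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import Karyotype
from .stats import TestResult, bh_fdr, chisq_gof
from scipy import stats as sps

__all__ = [
    "altered_chromosomes",
    "partition_degs",
    "chromosome_susceptibility",
    "overlap_degs",
    "CisTransPartition",
]


def altered_chromosomes(test_karyotype: Karyotype, reference_karyotype: Karyotype) -> set:
    """Chromosomes whose copy number differs between the karyotypes."""
    test_karyotype._check_universe(reference_karyotype)
    return {
        c
        for c in test_karyotype.copies
        if test_karyotype.copies[c] != reference_karyotype.copies[c]
    }


@dataclass
class CisTransPartition:
    """DEGs split by location relative to the altered chromosomes."""

    comparison: str
    altered: set
    cis: pd.DataFrame
    trans: pd.DataFrame
    n_unlocated: int = 0
    #: up-regulated DEGs on dosage-reduced chromosomes (dosage-opposing)
    cis_up_count: int | None = None
    trans_bias: TestResult | None = None

    @property
    def pct_trans(self) -> float:
        total = len(self.cis) + len(self.trans)
        return round(100.0 * len(self.trans) / total, 2) if total else 0.0

    def labeled_table(self) -> pd.DataFrame:
        """One row per DEG with its cis/trans label."""
        cis = self.cis.assign(effect="cis")
        trans = self.trans.assign(effect="trans")
        return pd.concat([cis, trans])


def partition_degs(
    deg_table: pd.DataFrame,
    genes: pd.DataFrame,
    altered: set,
    reduced: set | None = None,
    comparison: str = "",
) -> CisTransPartition:
    """Partition DEGs into cis (on an altered chromosome) and trans.

    DEGs whose gene is absent from the annotation are excluded with a
    warning and counted in ``n_unlocated``.  When ``reduced`` names the
    dosage-reduced chromosomes, the dosage-opposing count (up-regulated
    DEGs on those chromosomes) is reported.
    """
    degs = deg_table[deg_table["is_deg"]] if "is_deg" in deg_table else deg_table
    located = degs.index.intersection(genes.index)
    n_unlocated = len(degs) - len(located)
    if n_unlocated:
        warnings.warn(
            f"{n_unlocated} DEG(s) not present in the gene annotation; excluded",
            stacklevel=2,
        )
    degs = degs.loc[located]
    chrom = genes.loc[located, "chromosome"]
    cis_mask = chrom.isin(altered)
    cis, trans = degs[cis_mask], degs[~cis_mask]

    n_up = int((trans["direction"] == "up").sum())
    n_down = int((trans["direction"] == "down").sum())
    bias = chisq_gof([n_up, n_down]) if (n_up + n_down) > 0 else None

    cis_up = None
    if reduced is not None:
        on_reduced = chrom.isin(reduced)
        cis_up = int(((degs["direction"] == "up") & on_reduced).sum())

    return CisTransPartition(
        comparison=comparison,
        altered=set(altered),
        cis=cis,
        trans=trans,
        n_unlocated=n_unlocated,
        cis_up_count=cis_up,
        trans_bias=bias,
    )


def chromosome_susceptibility(
    deg_table: pd.DataFrame,
    expressed_genes,
    genes: pd.DataFrame,
    altered: set,
) -> pd.DataFrame:
    """Per-disomic-chromosome DEG enrichment table.

    For each chromosome not in ``altered``, a 2x2 chi-square (no
    continuity correction) of (DEG vs expressed non-DEG) x (this
    chromosome vs the other disomic chromosomes), BH-corrected across
    chromosomes.  ``expressed_genes`` is the universe of expressed gene
    ids the DEGs were drawn from.
    """
    degs = deg_table[deg_table["is_deg"]] if "is_deg" in deg_table else deg_table
    expressed = pd.Index(expressed_genes).intersection(genes.index)
    chrom = genes.loc[expressed, "chromosome"]
    disomic = [c for c in sorted(genes["chromosome"].unique()) if c not in altered]
    deg_ids = degs.index.intersection(expressed)
    deg_on = genes.loc[deg_ids, "chromosome"]
    # restrict the universe to disomic chromosomes
    in_universe = chrom.isin(disomic)
    total_exp = int(in_universe.sum())
    total_deg = int(deg_on.isin(disomic).sum())

    rows = []
    for c in disomic:
        n_exp = int((chrom == c).sum())
        n_deg = int((deg_on == c).sum())
        o_exp = total_exp - n_exp
        o_deg = total_deg - n_deg
        expected = n_exp * total_deg / total_exp if total_exp else 0.0
        table = np.array([[n_deg, n_exp - n_deg], [o_deg, o_exp - o_deg]], dtype=float)
        if total_deg == 0 or n_exp == 0 or o_exp == 0 or total_deg == total_exp:
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        rows.append(
            {
                "chromosome": c,
                "n_expressed": n_exp,
                "n_deg": n_deg,
                "expected_deg": expected,
                "chi2": float(stat),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out


def _membership_key(row, direction_aware: bool):
    return (row.Index, row.direction) if direction_aware else row.Index


def overlap_degs(deg_lists: dict, direction_aware: bool = False) -> dict:
    """Counts for every exclusive region of the 2- or 3-set Venn
    partition of the named DEG lists.

    Keys are "&"-joined sorted list names (e.g. ``"A"``, ``"A&B"``).
    With ``direction_aware`` the Venn elements are (gene, direction)
    pairs, so shared membership requires the same direction in every
    containing list.
    """
    if not 2 <= len(deg_lists) <= 3:
        raise ValueError("overlap_degs takes 2 or 3 named DEG lists")
    members = {}
    for name, table in deg_lists.items():
        degs = table[table["is_deg"]] if "is_deg" in table else table
        if degs.index.has_duplicates:
            dup = degs.index[degs.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene(s) within list {name!r}: {dup[:5]}")
        members[name] = {
            (gid, d) if direction_aware else gid
            for gid, d in zip(degs.index, degs["direction"])
        }
    names = sorted(members)
    regions = {}
    from itertools import combinations

    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(members[n] for n in combo))
            outside = set().union(
                set(), *(members[n] for n in names if n not in combo)
            )
            regions["&".join(combo)] = len(inside - outside)
    return regions
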