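"""Shared domain containers.

Tabular data travels as pandas objects with fixed schemas:

* gene annotation (``GeneModelSet``): DataFrame indexed by ``gene_id``
  with columns ``chromosome``, ``start``, ``end`` (1-based inclusive),
  ``exonic_length`` (bp) and ``subgenome`` ("A" or "C");
* count matrix: integer DataFrame, genes x samples;
* expression matrix: float FPKM DataFrame of the same shape;
* sample sheet: DataFrame with columns ``sample_id``, ``group``,
  ``replicate``.

Karyotypes get a small dataclass because copy-number bookkeeping is
what defines cis vs trans throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GENE_COLUMNS = ["chromosome", "start", "end", "exonic_length", "subgenome"]

COMPENSATION_CLASSES = ("non_expressed", "non_compensated", "compensated", "anti_compensated")

BIN_LABELS = ("non_expressed", "sub_threshold", "low", "medium", "high")


@dataclass(frozen=True)
class Karyotype:
    """Per-chromosome copy number of a sample group.

    Euploid chromosomes carry 2 copies; an absent alien chromosome is
    declared with 0 copies so that every group covers the same
    chromosome universe.
    """

    group: str
    copies: dict = field(default_factory=dict)

    def __post_init__(self):
        for chrom, c in self.copies.items():
            if c not in (0, 1, 2, 3):
                raise ValueError(f"copy number {c!r} for {chrom} outside {{0,1,2,3}}")

    def chromosomes(self) -> set:
        return set(self.copies)

    def is_euploid(self) -> bool:
        return all(c in (0, 2) for c in self.copies.values())

    def reduced_vs(self, reference: "Karyotype") -> set:
        """Chromosomes with fewer copies here than in ``reference``."""
        self._check_universe(reference)
        return {c for c in self.copies if self.copies[c] < reference.copies[c]}

    def _check_universe(self, other: "Karyotype") -> None:
        if set(self.copies) != set(other.copies):
            raise ValueError(
                f"karyotypes for {self.group!r} and {other.group!r} cover "
                "different chromosome universes"
            )


def validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table and return it unchanged."""
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene annotation missing columns: {missing}")
    if genes.index.has_duplicates:
        dupes = genes.index[genes.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in annotation: {dupes[:5]}")
    bad = genes[genes["start"] > genes["end"]]
    if len(bad):
        raise ValueError(f"start > end for genes: {bad.index[:5].tolist()}")
    if (genes["exonic_length"] <= 0).any():
        raise ValueError("exonic_length must be positive")
    return genes


def group_samples(samples: pd.DataFrame, group: str) -> list:
    """Sample ids belonging to ``group``; error if the group is unknown."""
    hits = samples.loc[samples["group"] == group, "sample_id"].tolist()
    if not hits:
        raise KeyError(f"unknown group {group!r}")
    return hits
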