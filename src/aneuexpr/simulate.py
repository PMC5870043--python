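"""Synthetic RNA-seq experiment with known dosage ground truth.

The generator emulates the three-line design used to study a
chromosome substitution in a two-subgenome crucifer: a euploid
reference (10 disomic A chromosomes, no C material), a monosomic alien
addition line (euploid complement plus one copy of C01) and a
substitution line (one A01 copy replaced by its C01 homoeolog, i.e.
A01 monosomic and C01 present at one copy), each with three biological
replicates.

Counts are negative-binomial with variance = mu + dispersion * mu^2.
A gene's expected count is proportional to

    baseline_fpkm * exonic_length * dosage_factor * 2**trans_log2fc

where the dosage factor is copies/2, except on the dosage-reduced
chromosome where a per-gene compensation state perturbs it: a
non-compensated gene keeps the pure one-dose factor 0.5, a compensated
gene is pulled back toward (or up to) its two-dose level, and an
anti-compensated gene falls below 0.5.  Expected counts are scaled per
sample so the expected library size is exact.  A configurable fraction
of genes on chromosomes that are disomic in an aneuploid group receive
trans-effect log2 fold changes, symmetric and truncated away from zero
so they are detectable at a twofold cutoff.

All randomness flows from one seed through deterministically spawned
substreams, so a fixed seed reproduces the experiment bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import Karyotype

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_experiment",
    "apply_compensation_factor",
    "default_karyotypes",
]

EUPLOID, ADDITION, SUBSTITUTION = "euploid", "addition", "substitution"

_PLANTED_CLASSES = ("non_compensated", "compensated", "anti_compensated")


def _chrom_names(n_chrom_A: int, n_chrom_C: int) -> list:
    return [f"A{i:02d}" for i in range(1, n_chrom_A + 1)] + [
        f"C{i:02d}" for i in range(1, n_chrom_C + 1)
    ]


def default_karyotypes(n_chrom_A: int = 10, n_chrom_C: int = 9) -> dict:
    """Copy-number maps for the euploid / addition / substitution trio."""
    chroms = _chrom_names(n_chrom_A, n_chrom_C)
    eu = {c: (2 if c.startswith("A") else 0) for c in chroms}
    add = dict(eu, C01=1)
    sub = dict(eu, A01=1, C01=1)
    return {EUPLOID: eu, ADDITION: add, SUBSTITUTION: sub}


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Baseline per-gene FPKM is log-normal: log2(FPKM) ~ Normal(mean, sd)
    with defaults centred on a few tens of FPKM and spread across the
    low/medium/high expression strata.  ``compensation_mix`` gives the
    (non_compensated, compensated, anti_compensated) proportions for
    genes on a dosage-reduced chromosome.  Compensation factors are
    drawn uniformly, by default in (0.5, 1.0] for compensated and
    [0.05, 0.5) for anti-compensated genes; explicit ranges override
    the defaults.
    """

    n_chrom_A: int = 10
    n_chrom_C: int = 9
    genes_per_chrom: int = 200
    replicates_per_group: int = 3
    base_log2_fpkm_mean: float = 5.0
    base_log2_fpkm_sd: float = 2.0
    nb_dispersion: float = 0.05
    library_size: float = 1e7
    dosage_multipliers: dict | None = None
    trans_effect_fraction: float = 0.1
    trans_effect_log2fc_sd: float = 1.5
    trans_effect_min_log2fc: float = 1.0
    compensation_mix: tuple = (0.64, 0.08, 0.28)
    compensated_factor_range: tuple | None = None
    anti_factor_range: tuple | None = None
    karyotypes: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        if not 0 <= self.trans_effect_fraction <= 1:
            raise ValueError("trans_effect_fraction must lie in [0, 1]")
        if self.trans_effect_log2fc_sd <= 0:
            raise ValueError("trans_effect_log2fc_sd must be positive")
        mix = np.asarray(self.compensation_mix, dtype=float)
        if mix.size != 3 or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
            raise ValueError("compensation_mix must be 3 non-negative proportions summing to 1")
        if self.dosage_multipliers is not None:
            for grp, m in self.dosage_multipliers.items():
                if any(v <= 0 for v in m.values()):
                    raise ValueError(f"dosage multiplier <= 0 for group {grp!r}")

    def group_karyotypes(self) -> dict:
        raw = self.karyotypes or default_karyotypes(self.n_chrom_A, self.n_chrom_C)
        return {g: Karyotype(g, dict(c)) for g, c in raw.items()}


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated matrices."""

    karyotypes: dict
    #: genes x groups expected FPKM-scale relative expression factor
    mean_factor: pd.DataFrame
    #: genes x samples expected counts (post library-size scaling)
    mean_counts: pd.DataFrame
    #: genes x groups true trans log2 fold change (0 where none)
    trans_lfc: pd.DataFrame
    #: genes x groups boolean trans-DEG flag
    is_trans: pd.DataFrame
    #: one row per (gene on a reduced chromosome, group): class + factor
    compensation: pd.DataFrame = field(default_factory=pd.DataFrame)

    def euploid_group(self) -> str:
        for g, k in self.karyotypes.items():
            if k.is_euploid():
                return g
        raise ValueError("no euploid group in truth")


def apply_compensation_factor(
    comp_class: str,
    base_factor: float,
    rng: np.random.Generator | None = None,
    compensated_range: tuple | None = None,
    anti_range: tuple | None = None,
) -> float:
    """Dosage factor for one gene given its compensation class.

    ``base_factor`` is the pure dosage factor (0.5 for monosomy).
    Non-compensated genes keep it; compensated genes draw uniformly
    above it (default (base, 1.0]); anti-compensated genes draw
    uniformly below it (default [0.1 * base, base)).
    """
    if base_factor <= 0:
        raise ValueError("base_factor must be positive")
    if comp_class == "non_compensated":
        return float(base_factor)
    rng = rng if rng is not None else np.random.default_rng()
    if comp_class == "compensated":
        lo, hi = compensated_range or (base_factor, 1.0)
        if not base_factor <= lo < hi:
            raise ValueError("compensated range must sit at or above base_factor")
        # uniform in (lo, hi]: 1 - random() lies in (0, 1]
        return float(lo + (hi - lo) * (1.0 - rng.random()))
    if comp_class == "anti_compensated":
        lo, hi = anti_range or (0.1 * base_factor, base_factor)
        if not 0 < lo < hi <= base_factor:
            raise ValueError("anti range must sit below base_factor")
        return float(lo + (hi - lo) * rng.random())
    raise ValueError(f"unknown compensation class {comp_class!r}")


def _make_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = _chrom_names(config.n_chrom_A, config.n_chrom_C)
    rows = []
    for chrom in chroms:
        lengths = np.exp(
            rng.uniform(np.log(300.0), np.log(10000.0), size=config.genes_per_chrom)
        ).astype(int)
        pos = 1
        for i, length in enumerate(lengths, start=1):
            span = int(1.5 * length)
            rows.append(
                {
                    "gene_id": f"g{chrom}_{i:04d}",
                    "chromosome": chrom,
                    "start": pos,
                    "end": pos + span - 1,
                    "exonic_length": int(length),
                    "subgenome": chrom[0],
                }
            )
            pos += span + 500
    return pd.DataFrame(rows).set_index("gene_id")


def _truncated_symmetric_lfc(
    rng: np.random.Generator, n: int, sd: float, min_abs: float
) -> np.ndarray:
    """Normal(0, sd) log2FCs conditioned on |lfc| >= min_abs."""
    out = rng.normal(0.0, sd, size=n)
    bad = np.abs(out) < min_abs
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) < min_abs
    return out


def simulate_experiment(config: SimConfig):
    """Generate (genes, counts, samples, truth) for one experiment.

    Returns the gene annotation table, the integer count matrix
    (genes x samples), the sample sheet and a :class:`SimTruth`
    consistent with the emitted matrices.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_base, rng_trans, rng_comp, rng_counts = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    genes = _make_genes(config, rng_genes)
    karyotypes = config.group_karyotypes()
    groups = list(karyotypes)
    euploid_groups = [g for g, k in karyotypes.items() if k.is_euploid()]
    if not euploid_groups:
        raise ValueError("karyotypes must declare a euploid group")
    # first euploid group is the reference; extra euploid groups (null
    # configurations) are treated like any other non-reference group
    euploid = euploid_groups[0]

    base_fpkm = 2.0 ** rng_base.normal(
        config.base_log2_fpkm_mean, config.base_log2_fpkm_sd, size=len(genes)
    )
    chrom_of = genes["chromosome"]

    # per-group dosage factor per gene
    factor = pd.DataFrame(1.0, index=genes.index, columns=groups)
    for g in groups:
        copies = karyotypes[g].copies
        mult = {c: copies.get(c, 2) / 2.0 for c in chrom_of.unique()}
        if config.dosage_multipliers and g in config.dosage_multipliers:
            mult.update(config.dosage_multipliers[g])
        factor[g] = chrom_of.map(mult).to_numpy()

    # compensation states on dosage-reduced chromosomes
    mix = np.asarray(config.compensation_mix, dtype=float)
    comp_rows = []
    for g in groups:
        if g == euploid:
            continue
        reduced = karyotypes[g].reduced_vs(karyotypes[euploid]) & {
            c for c in chrom_of.unique() if karyotypes[g].copies.get(c, 0) == 1
        }
        for chrom in sorted(reduced):
            idx = genes.index[chrom_of == chrom]
            classes = rng_comp.choice(_PLANTED_CLASSES, size=len(idx), p=mix)
            base = karyotypes[g].copies[chrom] / 2.0
            factors = np.array(
                [
                    apply_compensation_factor(
                        cls,
                        base,
                        rng=rng_comp,
                        compensated_range=config.compensated_factor_range,
                        anti_range=config.anti_factor_range,
                    )
                    for cls in classes
                ]
            )
            factor.loc[idx, g] = factors
            comp_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": idx,
                        "group": g,
                        "chromosome": chrom,
                        "comp_class": classes,
                        "factor": factors,
                    }
                )
            )
    compensation = (
        pd.concat(comp_rows, ignore_index=True)
        if comp_rows
        else pd.DataFrame(columns=["gene_id", "group", "chromosome", "comp_class", "factor"])
    )

    # trans-effect DEGs on chromosomes disomic in both the group and the euploid
    trans_lfc = pd.DataFrame(0.0, index=genes.index, columns=groups)
    is_trans = pd.DataFrame(False, index=genes.index, columns=groups)
    for g in groups:
        if g == euploid or config.trans_effect_fraction == 0:
            continue
        disomic = {
            c
            for c in chrom_of.unique()
            if karyotypes[g].copies.get(c, 0) == 2 and karyotypes[euploid].copies.get(c, 0) == 2
        }
        candidates = genes.index[chrom_of.isin(disomic)]
        flags = rng_trans.random(len(candidates)) < config.trans_effect_fraction
        chosen = candidates[flags]
        lfc = _truncated_symmetric_lfc(
            rng_trans, len(chosen), config.trans_effect_log2fc_sd, config.trans_effect_min_log2fc
        )
        trans_lfc.loc[chosen, g] = lfc
        is_trans.loc[chosen, g] = True

    # expected counts, scaled so each sample's expected total is library_size
    lengths = genes["exonic_length"].to_numpy(dtype=float)
    weight = factor.mul(2.0 ** trans_lfc).mul(base_fpkm * lengths, axis=0)
    mean_by_group = weight.div(weight.sum(axis=0), axis=1) * config.library_size

    samples = pd.DataFrame(
        [
            {"sample_id": f"{g}_{r}", "group": g, "replicate": r}
            for g in groups
            for r in range(1, config.replicates_per_group + 1)
        ]
    )
    mean_counts = pd.DataFrame(
        {row.sample_id: mean_by_group[row.group] for row in samples.itertuples()},
        index=genes.index,
    )

    mu = mean_counts.to_numpy(dtype=float)
    shape = 1.0 / config.nb_dispersion
    lam = rng_counts.gamma(shape, scale=mu * config.nb_dispersion)
    counts = pd.DataFrame(
        rng_counts.poisson(lam).astype(np.int64),
        index=genes.index,
        columns=mean_counts.columns,
    )

    truth = SimTruth(
        karyotypes=karyotypes,
        mean_factor=factor,
        mean_counts=mean_counts,
        trans_lfc=trans_lfc,
        is_trans=is_trans,
        compensation=compensation,
    )
    return genes, counts, samples, truth
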