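# Methods

## The measurement model

All analysis starts from a gene-level fragment count matrix.  FPKM is
computed self-containedly as count · 10⁹ / (exonic_length ·
column_sum); "mapped-read" totals from an aligner are never seen, so
the per-sample denominator is the column sum of the matrix itself.
FPKM and RPKM are treated as the same quantity (paired-end fragments
are the counting unit throughout).  FPKM inverts exactly back to
counts, which the test suite asserts on every run.

Expression bins partition [0, ∞): 0 → non_expressed, (0, 0.1] →
sub_threshold, (0.1, 10] → low, (10, 100] → medium, (100, ∞) → high.
The published strata use strict inequalities that leave the edge
values 0.1, 10 and 100 unassigned; upper edges are closed here so the
function is total, and the sub_threshold bin gives the interval
between zero and the lowest stratum floor a home.

## Dosage scanning

For a test group against the euploid reference, each chromosome's
per-gene log₂ ratio of mean FPKM is computed over genes expressed
(mean FPKM > 0) in both groups.  The chromosome's copy number is the
c ∈ {1, 2, 3} whose centre log₂(c/2) is nearest the median ratio —
the minimal formalisation of reading a box plot, and parameter-free.
When at least five chromosomes are callable, each chromosome's median
is judged relative to the consensus level — the median of the
per-chromosome medians — before matching: FPKM is relative, so
unbalanced expression changes shift every chromosome by a common
offset, and comparing each box against the others is how a
chromosome-level box plot is actually read.  On small hand-built
genomes (fewer than five callable chromosomes) no consensus exists
and the raw median is used.  A Wilcoxon signed-rank test of the
ratios against zero is reported as supporting evidence only; no
threshold is tied to it.  Chromosomes
with fewer than `min_genes` (default 10) usable genes get `no_call`;
in particular an alien chromosome absent from the reference has no
defined ratio and is described by its test-only expression instead.

## Differential expression

The decision rule is twofold change with BH q < 0.05.  The test is
Welch's t between the groups' log₂(FPKM + 1) replicate values, with
fold change log₂((m_t + 1)/(m_r + 1)); genes unexpressed in both
groups are neither tested nor counted in the BH family.  This is a
deliberate substitution for a negative-binomial count model: the test
is fully specified, uses replicate variance from both groups, and the
downstream statistics (bias tests, partitions, overlaps) consume only
the calls.  The substitution is stated in the CLI help.

**Composition correction.**  FPKM is a relative abundance: when
expression changes are not balanced — an alien chromosome appearing,
or trans effects whose linear-scale mean E[2^L] exceeds 1 — every
unchanged gene's FPKM shifts by the inverse of the total change, and
the fold-change distribution moves off zero.  `call_degs` therefore
estimates that shift as the median log₂ ratio over tested genes (the
assumption being that most genes are unchanged) and removes it,
splitting the rescaling symmetrically between the two groups so that
swapping test and reference still negates every fold change exactly.
This is the FPKM-scale analogue of size-factor (median-of-ratios)
normalisation in count-based DE tools, and without it the empirical
FDR on simulated data with planted asymmetric effects is badly
inflated.  A `center_log2fc=False` switch restores the uncorrected
ratios.

## Cis/trans partition and bias tests

A DEG is cis iff its gene lies on a chromosome whose copy number
differs between the compared karyotypes — including the alien
chromosome's own genes — and trans otherwise.  Directional bias
within any DEG set is the uncorrected χ² goodness-of-fit test on the
(up, down) counts against 50:50; the uncorrected form reproduces the
published bias p-values from the corresponding count tables exactly
at their printed precision, which the Yates-corrected form does not.
Per-chromosome susceptibility is a 2×2 Pearson χ² (no continuity
correction) of DEG membership against chromosome membership among
expressed genes on disomic chromosomes, BH-corrected across
chromosomes.  Venn overlaps across two or three comparisons count
every exclusive region; in direction-aware mode the elements are
(gene, direction) pairs, so a gene up in one comparison and down in
another is not shared.  Up-regulated DEGs on a dosage-reduced
chromosome are reported as a named dosage-opposing count; no
positional clustering test is attempted.

## Compensation classification

Each gene on the monosomic chromosome is tested against the pure
dosage null H₀: mean_test = mean_ref / 2 with a Welch two-sample t
between the test replicates and the halved reference replicates on
the log₂(x + 1) scale (a linear-scale variant is a switch).  With
α = 0.05: not rejected → non_compensated; rejected above/below the
halved mean → compensated / anti_compensated.  The halving expresses
the null exactly while using replicate variance from both groups,
which is well defined at n = 3.  Genes with mean reference FPKM ≤ 0.1
are non_expressed and not tested; the threshold aligns with the
lowest expression-stratum floor, since no explicit definition exists
in the source material.  Replicate vectors that are constant on both
sides leave the statistic undefined; such genes are classified by the
sign of the deviation and flagged degenerate.  The cross-tab bins
classified genes by the *reference* group's mean expression and tests
each row's (compensated + anti_compensated) vs non_compensated counts
with the equal-expectation χ².

Raising α can only move genes out of non_compensated, never into it
(monotonicity, asserted in tests).

## Statistical primitives

χ² goodness-of-fit and 2×2 contingency tests are Pearson's, with
Yates correction available but off by default everywhere.  For k = 2
the uncorrected GOF p equals 2·Φ(−√χ²), used as a closed-form
cross-check.  BH adjustment is the step-up q_(i) = min_{j≥i} p_(j)·n/j
capped at 1 (statsmodels' implementation, cross-checked against a
direct evaluation).  The Wilcoxon signed-rank test drops zero
differences, then uses the exact conditional null distribution for
n ≤ 25 — computed by dynamic programming over the observed (possibly
tied, average) ranks, equivalent to enumerating all 2ⁿ sign
assignments — and the normal approximation with tie correction and a
0.5 continuity correction above.  P-values are kept in full double
precision; no reporting floor is imposed.

## The simulator

`simulate_experiment` emulates the three-line design: euploid
(A01–A10 disomic, C01–C09 absent), addition (+1 copy of C01) and
substitution (A01 monosomic, C01 at one copy), three replicates each.
Counts are negative-binomial via the gamma–Poisson mixture with
variance μ + φμ², one global dispersion φ (default 0.05, a typical
biological-replicate value).  A gene's weight is

    baseline_fpkm · exonic_length · dosage_factor · 2^trans_log2fc

with baseline log₂ FPKM ~ Normal(5, 2), exonic lengths log-uniform on
[300, 10000] bp, and dosage factor copies/2 — except on the reduced
chromosome, where each gene draws a compensation class from
`compensation_mix` (default 0.64/0.08/0.28 for
non/compensated/anti-compensated, matching the observed class
proportions among expressed one-dose genes in the motivating study)
and a factor: exactly 0.5 for non-compensated, uniform (0.5, 1.0] for
compensated, uniform [0.05, 0.5) for anti-compensated (ranges
configurable).  Trans-effect DEGs are drawn on chromosomes disomic in
both the group and the reference (default 10% of candidate genes)
with symmetric log₂FC ~ Normal(0, 1.5) truncated to |log₂FC| ≥ 1 so
they are detectable at the twofold cutoff.  Expected counts are
scaled per sample so the expected library size (default 10⁷
fragments, in the range of typical bulk libraries) is exact —
sequencing depth is set by the machine, not the transcriptome.  One
seed drives everything through deterministically spawned substreams;
identical seeds give bit-identical output.

Two consequences of this design are worth knowing.  First, because
per-sample depth is fixed, unbalanced planted effects shift all
relative abundances: at defaults the aneuploid groups' FPKM carries a
genome-wide offset of roughly −0.2 log₂ against the euploid.  This is
a real property of relative measures (and one reason a genome-wide
down-bias accompanies an added chromosome); the dosage caller's
consensus level removes it, as does the DE caller's median
centering.  Properties that isolate the pure dosage mechanism
(e.g. the median log₂ ratio of non-compensated one-dose genes sitting
at −1 ± 0.15) are therefore checked with trans effects disabled.
Second, the realised FPKM scale ends up a small constant factor above
the nominal baseline law, because normalisation divides by the
expressed fraction of the annotation only.

What the generator does not emulate: read-level artefacts, mapping
ambiguity between homoeologs, gene-specific dispersion, correlated
co-regulation, batch structure.  Passing the recovery tests shows the
statistics behave as designed under the NB model, not that the
pipeline is robust to those real-data complications.

## Validation experiments and problem sizes

The test suite and the acceptance script size their simulations to
run comfortably on one CPU:

* karyotype recovery: 20 experiments at 200 genes/chromosome,
  dispersion 0.2 — the full karyotype (A01 reduced in the
  substitution line, nothing reduced in the addition line) must be
  recovered in ≥ 95% of them;
* DE recovery: ~1000-gene experiments with ~100 planted |log₂FC| ≥ 2
  trans DEGs at dispersion 0.05, n = 3, pooled over seeds — recall
  ≥ 0.9 at empirical FDR ≤ 0.1;
* compensation recovery: planted factors uniform (0.9, 1.0] for
  compensated and [0.05, 0.25] for anti-compensated at dispersion
  0.05, n = 3, trans effects off, pooled over seeds — ≥ 80% of
  deviating (compensated + anti-compensated) genes recovered with
  ≤ 10% false rejection among non-compensated genes.  Pooling the two
  deviating classes is the operative reading: at n = 3 and α = 0.05
  the per-gene power for a factor-0.95 compensated gene is ~0.6 (the
  1.9-fold deviation from the halved null sits at the edge of what a
  three-replicate t-test resolves), while anti-compensated genes at
  factor ≤ 0.25 are recovered at ~0.9; the per-class rates are
  reported alongside the pooled one.

## Known limitations

* The Welch-on-FPKM DE test has no count-model shrinkage; at n = 3 it
  is conservative for dim genes and its fold changes are attenuated
  by the +1 pseudocount below a few FPKM.
* Cis/trans assignment is purely positional; a trans-regulated gene
  that happens to sit on the altered chromosome is counted cis.
* The compensation classifier inherits the t-test's power profile:
  subtle compensation (factor just above 0.5) is mostly labelled
  non-compensated, mirroring the prevalence of that class among
  low-expressed genes in real data.
* Median centering assumes most genes are unchanged; it would
  mis-centre an experiment where the majority of the transcriptome
  genuinely moves in one direction.
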