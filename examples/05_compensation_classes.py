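"""Classify one-dose genes on the monosomic chromosome.

The null hypothesis per gene is a pure dosage effect (test mean equals
half the euploid mean).  Rejection upward = compensated, downward =
anti-compensated; otherwise non-compensated.  The cross-tab stratifies
by the euploid expression level.
"""

import aneuexpr as ax

cfg = ax.SimConfig(seed=1, genes_per_chrom=150)
genes, counts, samples, truth = ax.simulate_experiment(cfg)
expr = ax.compute_fpkm(counts, genes)

calls = ax.classify_chromosome(
    expr, genes, samples, test="substitution", reference="euploid",
    chromosome="A01",
)
tab = ax.compensation_crosstab(calls)

print("class proportions over all A01 genes:")
for cls, d in tab.class_proportions.items():
    print(f"  {cls:18s} {d['count']:4d}  ({d['pct']}%)")
print("\ncounts by euploid expression bin:")
print(tab.counts.to_string())
print("\nrow percentages:")
print(tab.row_pct.to_string())
for b, r in tab.row_bias.items():
    if r is not None:
        print(f"bias p ({b}): {r.p:.3g}")
print("\nThe bias test per row asks whether deviating genes (compensated")
print("+ anti-compensated) outnumber non-compensated ones at that level.")
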