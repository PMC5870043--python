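"""Simulate the three-line experiment and look at the ground truth.

Generates a euploid reference, a monosomic alien addition line (extra
C01) and a substitution line (one A01 replaced by C01), three
replicates each, with negative-binomial counts.
"""

import aneuexpr as ax

cfg = ax.SimConfig(seed=1, genes_per_chrom=100)
genes, counts, samples, truth = ax.simulate_experiment(cfg)

print(f"genes: {len(genes)}  samples: {len(samples)}")
print(f"library sizes:\n{counts.sum(axis=0)}\n")
print("karyotype of the substitution line (non-euploid entries):")
for chrom, copies in sorted(truth.karyotypes["substitution"].copies.items()):
    if copies != 2:
        print(f"  {chrom}: {copies} copies")

comp = truth.compensation
sub = comp[comp.group == "substitution"]
print("\nplanted compensation classes on the one-dose chromosome A01:")
print(sub["comp_class"].value_counts().to_string())
n_trans = int(truth.is_trans["substitution"].sum())
print(f"\nplanted trans-effect DEGs in the substitution line: {n_trans}")
# Every downstream module is validated against exactly these tables:
# the karyotype is what the dosage scan must recover, the classes are
# what the compensation classifier must recover.
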