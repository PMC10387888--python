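"""From SNP summary statistics to gene-level p-values.

Builds a six-SNP toy dataset, keeps nominally significant variants
(p < 0.05, strict), applies functional weighting p_w = p / 10**FS, maps SNPs
to two genes by physical position and aggregates with the min-p (max chi2)
statistic.
"""

from pathnetgwas import (
    GeneModel,
    SnpRecord,
    apply_functional_weighting,
    filter_by_pvalue,
    map_snps_to_genes,
    score_genes,
)

snps = [
    SnpRecord("1", 150_000, "A", "G", 0.001, rsid="rs1"),
    SnpRecord("1", 160_000, "C", "T", 0.04, rsid="rs2", fs=0.8),
    SnpRecord("1", 170_000, "G", "A", 0.05, rsid="rs3"),   # dropped: not < 0.05
    SnpRecord("2", 150_000, "T", "C", 0.02, rsid="rs4"),
    SnpRecord("2", 151_000, "A", "C", 0.60, rsid="rs5"),   # dropped
    SnpRecord("2", 152_000, "G", "T", 0.03, rsid="rs6", fs=0.3),
]
genes = [
    GeneModel("GENE_A", "1", 140_000, 180_000, window=10_000),
    GeneModel("GENE_B", "2", 145_000, 155_000, window=10_000),
]

kept = apply_functional_weighting(filter_by_pvalue(snps, cutoff=0.05))
print(f"{len(kept)} of {len(snps)} SNPs pass the p < 0.05 filter")
for r in kept:
    print(f"  {r.rsid}: p={r.p_gwas:.3f} fs={r.fs} -> p_w={r.p_w:.4f}")

table = score_genes(map_snps_to_genes(kept, genes), "toy", kind="max_chi2")
print("\ngene scores (min weighted p per gene):")
print(table.to_frame().to_string(index=False))
# Each gene's p is its best weighted SNP p-value; rs2's functional score
# (0.8) lifts it past rs1, so GENE_A is driven by the weighted rs2.
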