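# pathnetgwas

Pathway- and network-oriented post-GWAS analysis for complex diseases.

Single-variant association tests leave most of the heritability of complex
disorders unexplained: risk is spread over many variants of mild effect whose
gene products act together in protein complexes and pathways. `pathnetgwas`
implements a workflow that aggregates that diffuse evidence along biological
structure. It is aimed at statistical geneticists and systems biologists who
have GWAS **summary statistics** (no genotypes), a protein–protein
interaction (PPI) network, and a pathway collection (GMT), and who want
disease-associated modules and pathways rather than single hits.

## The method

1. **SNP filtering and functional weighting.** Variants are kept when
   p < 0.05 (strict), then weighted by a functional score FS ∈ [0, 1]:
   p_w = p<sub>GWAS</sub> / 10<sup>FS</sup>.
2. **Gene scores.** SNPs map to genes by physical distance (interval ±50 kb
   by default). Per gene, either the maximum of the 1-df χ² transforms
   (equivalently the minimum SNP p) or the sum of χ² statistics gives a gene
   p-value; Fisher's combined test, χ² = −2 Σ ln p<sub>i</sub> on 2m df,
   merges m datasets over their common genes.
3. **Active subnetworks (top-down).** Gene p-values become
   z<sub>i</sub> = Φ<sup>−1</sup>(1 − p<sub>i</sub>); a subnetwork A of size k
   scores z<sub>A</sub> = Σ z<sub>i</sub> / √k, calibrated against a
   Monte-Carlo null of random size-k node sets:
   s<sub>A</sub> = (z<sub>A</sub> − μ<sub>k</sub>) / σ<sub>k</sub>. A greedy
   hill-climb from every seed node keeps subnetworks with s<sub>A</sub> ≥ 3.
4. **DIAMOnD expansion (bottom-up).** From known seed genes, the node whose
   links into the module are most hypergeometrically surprising —
   p(k, k<sub>s</sub>) = C(s₀, k<sub>s</sub>) C(N−s₀, k−k<sub>s</sub>) / C(N, k),
   upper-tailed — joins at each step.
5. **Enrichment and consensus.** Modules are tested against pathways by the
   hypergeometric tail with Bonferroni or Benjamini–Hochberg correction;
   pathways significant (p<sub>adj</sub> < 0.05) in every dataset form the
   strict consensus.
6. **Pathway network and clusters.** Pathway pairs are linked when their
   co-membership Cohen's kappa ≥ 0.15; the subnetwork search reruns on this
   pathway graph with enrichment p-values as node significance, and
   subnetworks larger than 50 pathways are subdivided by MCODE-style dense
   clustering.
7. **Cross-dataset similarity.** Module sets from two datasets are compared
   through their shared-gene contingency table:
   NMI<sub>SUM</sub> = 2 I(U,V) / (H(U) + H(V)) ∈ [0, 1].

A seeded synthetic-fixture generator (scale-free PPI, planted low-p module,
pathway collection with a designated disease pathway) provides known-truth
inputs for every stage; no external downloads are needed.

## Worked example

```bash
python examples/02_active_subnetworks.py
```

```
447 subnetworks reach the score cutoff s_A >= 3
top subnetwork: k=32, z_A=24.85, s_A=16.71
  contains 25/25 planted genes (Jaccard 0.78)
```

A 500-protein synthetic interactome carries a planted 25-gene module with
p ≤ 10⁻⁶. The top-scoring subnetwork (32 genes) sits 16.7 calibrated-null
standard deviations above random node sets and contains the entire planted
module plus seven borderline neighbors — exactly the behavior the greedy
search is designed for: strong genes recruit their interaction partners.
The other `examples/` scripts walk through gene scoring, DIAMOnD expansion,
enrichment consensus, pathway clustering and NMI comparison the same way.

There is also a thin CLI mirroring the library
(`pathnetgwas simulate | gene-scores | combine | subnetworks | diamond |
enrich | pathway-net | pathway-clusters | compare | run`).

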