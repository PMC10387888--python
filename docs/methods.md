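# Methods

This note records the models implemented in `pathnetgwas`, the parameter
choices that matter, the design decisions taken where the design was open,
and what the synthetic fixtures do and do not establish.

## Gene-level evidence from summary statistics

Variants are filtered at p < 0.05 with a **strict** inequality, collecting
nominally significant evidence of mild effects. Functional weighting divides
the association p-value by 10^FS with FS ∈ [0, 1], so a maximally damaging
variant gains one order of magnitude; a missing score means FS = 0 and leaves
the p-value untouched. P-values are clamped to [1e-300, 1] on ingest (logged)
so downstream logs and quantile transforms stay finite.

SNPs are assigned to genes by physical position against 0-based half-open
BED intervals extended by a flanking window on each side. The window default
is **50 kb**, a common post-GWAS mapping choice; it is configurable because
no single value suits every annotation. Summary-statistic positions are
1-based and converted internally; chromosome labels are normalized by
stripping a case-insensitive `chr` prefix.

Two aggregation statistics are offered. `max_chi2` takes the maximum of the
1-df inverse-χ² transforms, whose p-value is exactly the minimum SNP p-value;
`sum_chi2` compares Σᵢ χ²₁(pᵢ) against a χ² with one df per SNP. Neither
corrects for LD or gene size — the LD-aware correction of genotype-panel
methods is intentionally out of scope, and `statistic_kind` records which
uncorrected statistic produced every gene p so downstream consumers cannot
confuse the two. Under the null both statistics give uniform gene p-values
(property-tested); with real LD they would be anti-conservative, which is the
main caveat when moving from fixtures to real data.

Fisher's combined test, χ² = −2 Σ ln pᵢ on 2m df, merges m datasets and is
applied only to genes scored in **every** dataset, mirroring common-gene
meta-analysis practice.

## Active-subnetwork search

Node significance enters as z = Φ⁻¹(1 − p), computed as −Φ⁻¹(p) for
precision at tiny p and clamped to p ∈ [1e-300, 1 − 1e-16] so z stays finite
at p = 1. A size-k subnetwork scores z_A = Σz/√k — exactly N(0,1) for iid
standard-normal node scores — and is calibrated against an empirical null:
for each k, `n_samples` (default 10,000) random node sets are drawn from the
score pool and s_A = (z_A − μ_k)/σ_k standardizes against their moments.

Calibration draws ignore topology (random node sets, not random connected
sets). This matches the classical scoring scheme, keeps the null cheap, and
is conservative: connected sets in a network with clustered signal score
higher than random sets, so the calibrated null understates extreme
subnetworks rather than inflating them. Sampling is vectorized: each sample
is a random permutation prefix (pools up to a few thousand) or a
duplicate-rejected index draw (large pools); prefixes across sizes share
draws, which leaves every size's marginal distribution exact and only
correlates the *estimates* μ_k across k, which nothing downstream uses
jointly. A σ floor of 1e-8 guards degenerate (constant) pools.

The greedy search runs one hill-climb per seed; every scored node seeds by
default. At each step the candidate neighbor maximizing s_A joins — since
μ_{k+1} and σ_{k+1} are fixed, this is exactly the neighbor with the largest
z, implemented with a max-heap — and the climb stops at the first
non-improving step or at `max_size` (default 300, above typically observed
module sizes). Ties break lexicographically on node id, which makes the
search deterministic and equivariant under relabeling. Unscored neighbors
are excluded and logged. Identical node sets reached from different seeds
collapse to one record; overlapping-but-distinct subnetworks are all
reported. The score cutoff s_A ≥ 3 is applied to the greedy-maximized score
as stated; note the calibration is for random sets, so the cutoff on an
optimized score is anti-conservative in the usual way of active-subnetwork
methods.

## DIAMOnD expansion

The connectivity significance of a candidate with degree k and k_s links
into the current module of size s₀ in an N-node network is the upper
hypergeometric tail Σ_{i≥k_s} C(s₀,i) C(N−s₀,k−i)/C(N,k), computed in log
space (gammaln + logsumexp) and verified against exact rational enumeration
to ~1e-14 relative error. Candidates are restricted to nodes with ≥1 edge
into the module (k_s = 0 carries p = 1 and the iteration grows a
neighborhood); p-values are recomputed against the grown module at every
step, per the original algorithm. Ties break by smaller p, then larger k_s,
then lexicographic id. The original seed-link weighting parameter α is not
implemented (α = 1 behavior only). Module-size presets of 200 and 500
additions are exposed through the pipeline configuration.

## Enrichment, correction and consensus

Over-representation uses the same hypergeometric tail with universe f,
pathway size g, query size d and overlap k. The universe defaults to the
union of the collection's genes (the annotation universe); query genes
outside it are dropped from d and logged. Bonferroni is min(1, m·p);
Benjamini–Hochberg is the standard step-up (delegated to scipy and
cross-checked against statsmodels in the tests). Significance means
p_adj < α with α = 0.05. Results sort deterministically by
(p_adj, p_raw, pathway id).

A dataset usually contributes many modules. Its pathway-level p is the
**minimum adjusted p over the dataset's modules** — an explicit choice where
several aggregations (frequency, rank products) would also be defensible;
minimum-p is the most sensitive and is recorded as such. Strict consensus
keeps pathways significant in every dataset; a `min_datasets` relaxation
reports at-least-k-of-n support.

## Kappa pathway network

The binary gene-term matrix over the union of pathway genes yields, for each
pathway pair, co-membership counters (cn11, cn10, cn01, cn00). Observed
agreement is G = (cn11+cn00)/total; chance agreement uses the standard
product-of-margins form C = [(cn11+cn01)(cn11+cn10) +
(cn00+cn10)(cn00+cn01)]/total², and K = (G−C)/(1−C), with K ≡ 1 in the
identical-margin degenerate case. Pathways are linked when K ≥ 0.15 — the
threshold is **inclusive**; the value 0.15 is the conventional operating
point giving a useful node-to-edge ratio — self-pairs are excluded and
isolated pathways remain as nodes. The all-pairs computation is a single
set of matrix products.

## Pathway subnetworks and MCODE clusters

The active-subnetwork machinery reruns on the pathway graph with
dataset-aggregated enrichment p-values as node significance (missing
pathways get p = 1, logged) and a calibration recomputed on the pathway
pool. Subnetworks larger than **50** pathways (strictly) are subdivided by a
molecular-complex-detection scheme:

* **Vertex weight** = (highest k-core number of the open neighborhood's
  induced subgraph) × (density of that k-core subgraph); isolated nodes and
  edge-free neighborhoods weigh 0.
* **Growth** seeds at the heaviest unassigned node and repeatedly admits the
  heaviest adjacent candidate whose weight ≥ seed weight × (1 − cutoff),
  with cutoff 0.2, **and** whose edges into the current cluster number at
  least min(k_core, cluster size), k_core = 2. The connectivity guard is the
  package's reading of the k-core parameter: with weight-threshold traversal
  alone, two equally dense regions joined by one bridge edge merge into one
  cluster (all vertex weights tie), whereas requiring two edges into the
  growing cluster keeps each clique with its own bridge endpoint — the
  behavior dense-cluster decomposition is meant to have.
* **Haircut** trims the grown cluster to its 2-core (iterated degree-1
  removal — a single pass can expose new degree-1 nodes, so the fixpoint is
  taken). **Fluff** exists as a documented optional post-step and is off by
  default. Grown nodes are consumed even if the haircut trims them, keeping
  clusters disjoint.
* **Cluster score** = internal density × node count, the conventional
  complex-scoring heuristic; ranks follow scores with lexicographic
  tie-breaks. In the pipeline, clusters are ordered first by their parent
  subnetwork's s_A, then by cluster score, so "the top cluster" is the densest
  piece of the most significant pathway subnetwork.

## NMI comparison

Module sets may overlap, so the contingency table of shared-gene counts is
taken as the primitive: margins and the grand total derive from the table
itself, which keeps the implied joint distribution well-formed and I(U,V)
non-negative even for non-partitions (the partition interpretation is then
heuristic, and documented as such). Natural logarithms are used throughout
(the base cancels in NMI_SUM); 0·log 0 = 0; a table with no shared genes is
an error directing the caller to report "no overlap" rather than a number;
the zero-entropy single-block case is defined as NMI = 1 for continuity.
NMI_SUM is clamped to [0, 1] against floating error. For true partitions the
implementation agrees with scikit-learn's arithmetic-averaged NMI to 1e-10.

## Synthetic fixtures: what they emulate and what they do not

`FixtureSpec` defaults define the study conditions used by the tests and the
acceptance script: a 500-gene preferential-attachment PPI with mean degree 10
(edge count m(n−m), m = 5 — heavy-tailed degrees are what stress the
hypergeometric connectivity test), a planted connected module of 25 genes
(30 in the bottom-up setting) at p ≤ 1e-6, 60 pathways of 10–40 genes, an
overlap rate of 0.15 through a 50-gene shared pool, three summary-statistic
datasets with 1–8 SNPs per gene, and functional scores on a random 5% of
SNPs.

The planted module is collected by seeded BFS and then densified with random
intra-module edges to a mean internal degree of 6. Pure preferential
attachment has no community structure, so without densification no node set
would carry internal connectivity in excess of degree expectation — precisely
the signal connectivity-based module detection measures; an internal degree
of 6 against background mean degree 10 corresponds to a moderate mixing
level (roughly half of a member's edges stay inside), in line with
community-detection benchmarks. Gene-level signal is injected first and then
distributed to SNPs — one SNP per gene carries exactly the gene's target p
and the rest draw Uniform(p, 1) — so gene-score correctness is testable
independently of the SNP layer. The pathway collection designates one
disease pathway holding ~90% of the planted genes plus ~20% impurity, and
four satellite pathways borrowing ~30% of its genes, which gives the kappa
network a signal neighborhood; the trio of datasets shares the planted truth
with independent noise.

What passing these fixtures shows: the statistics are computed correctly,
the searches recover signal of the planted kind, the pipeline is
deterministic end to end. What they do not show: robustness to LD (no LD is
simulated, and the gene scores are deliberately uncorrected), to annotation
bias, to PPI false edges/ascertainment, or to the anti-conservativeness of
cutoff-on-optimized-score selection — all properties that real-data studies
must assess separately.

## Numerical and reproducibility choices

All randomness flows through numpy Generators seeded from explicit integers;
fixture stages use independent named streams so adding a stage never
perturbs another. Reruns with the same configuration and seed are
byte-identical (the run manifest contains parameters and no timestamps).
Hypergeometric tails are summed in log space; p→z uses −Φ⁻¹(p) rather than
Φ⁻¹(1−p) to avoid cancellation at small p. Tie-breaks everywhere are
lexicographic on identifiers, making every search order-independent of hash
or insertion order. Problem sizes in the tests and acceptance script (500
nodes, 10,000 Monte-Carlo samples, 20 replicates) were chosen so each
statistical band has comfortable margin at typical seeds while the whole
suite stays desk-scale.
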