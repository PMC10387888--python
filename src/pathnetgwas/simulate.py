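"""Seeded synthetic fixtures: PPI graphs, planted disease modules, pathway
collections with controlled overlap, and GWAS summary statistics.

The generator emulates the structure the analysis assumes rather than any
real cohort: a scale-free interactome (preferential attachment, so degree
heterogeneity stresses the hypergeometric connectivity test), a planted
connected low-p module grown by snowball sampling that prefers neighbors with
many links into the module (disease genes cluster in the interactome), a
pathway collection with one designated disease pathway carrying most planted
genes plus satellite pathways sharing part of its gene set (giving the kappa
network a signal neighborhood), and a trio of summary-statistic datasets
whose gene-level minimum p-values match the planted gene p-values exactly.
Everything is bit-reproducible from ``FixtureSpec.rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .gwas import GeneModel

# independent, named RNG streams per stage
_STREAMS = {"ppi": 1, "module": 2, "pathways": 3, "sumstats": 4}

N_SATELLITE_PATHWAYS = 4
SATELLITE_BORROW_FRACTION = 0.3
DISEASE_PATHWAY_PURITY = 0.9
HUB_POOL_SIZE = 50
FS_FRACTION = 0.05


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic fixture bundle."""

    rng_seed: int = 17
    n_genes: int = 500
    ppi_mean_degree: float = 10.0
    n_pathways: int = 60
    pathway_size_range: tuple[int, int] = (10, 40)
    overlap_rate: float = 0.15
    planted_module_size: int = 25
    planted_p_max: float = 1e-6
    module_internal_degree: float = 6.0
    snps_per_gene_range: tuple[int, int] = (1, 8)
    n_datasets: int = 3
    n_seed_genes: int | None = None  # default: planted_module_size // 3

    def __post_init__(self) -> None:
        if self.planted_module_size > self.n_genes:
            raise ValueError("planted_module_size must be <= n_genes")
        if not (0.0 <= self.overlap_rate < 1.0):
            raise ValueError("overlap_rate must be in [0,1)")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")

    def seed_count(self) -> int:
        return self.n_seed_genes or max(1, self.planted_module_size // 3)


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth planted into a fixture bundle."""

    planted_gene_ids: frozenset
    seed_subset: frozenset
    planted_pathway_ids: frozenset = frozenset()
    disease_pathway_id: str | None = None


def _rng(spec: FixtureSpec, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stage], spec.rng_seed])


def gene_ids(spec: FixtureSpec) -> list[str]:
    return [f"G{i:04d}" for i in range(spec.n_genes)]


def simulate_ppi(spec: FixtureSpec) -> nx.Graph:
    """Connected scale-free graph via preferential attachment.

    With attachment parameter m = mean_degree / 2 the edge count is
    m (n - m), i.e. a node-to-edge ratio near 1 : mean_degree/2.
    """
    m = max(1, round(spec.ppi_mean_degree / 2))
    nx_seed = int(_rng(spec, "ppi").integers(0, 2**31 - 1))
    raw = nx.barabasi_albert_graph(spec.n_genes, m, seed=nx_seed)
    mapping = dict(zip(range(spec.n_genes), gene_ids(spec)))
    return nx.relabel_nodes(raw, mapping)


def plant_module(
    graph: nx.Graph, spec: FixtureSpec
) -> tuple[dict[str, float], FixtureTruth]:
    """Plant a connected low-p module and draw background gene p-values.

    Members are collected by seeded BFS from a random root; the induced
    subgraph is then densified with random intra-module edges (added to
    ``graph`` in place) until its mean internal degree reaches
    ``module_internal_degree``. Preferential attachment alone has no
    community structure, so without densification no node set would carry
    the excess internal connectivity that disease modules show and that
    connectivity-based module detection measures; the default internal
    degree of 6 against a background mean degree of 10 corresponds to a
    moderate mixing level (about half of a member's edges stay inside),
    in line with community-detection benchmark practice. Planted genes draw
    p ~ Uniform(0, planted_p_max); background genes p ~ Uniform(0, 1).
    """
    rng = _rng(spec, "module")
    nodes = sorted(graph.nodes)
    root = nodes[int(rng.integers(len(nodes)))]
    module = {root}
    queue = [root]
    while len(module) < spec.planted_module_size:
        if not queue:
            raise ValueError("component exhausted before reaching requested module size")
        cur = queue.pop(0)
        nbrs = np.array(sorted(n for n in graph[cur] if n not in module))
        rng.shuffle(nbrs)
        for nb in nbrs:
            if len(module) >= spec.planted_module_size:
                break
            module.add(str(nb))
            queue.append(str(nb))

    members = sorted(module)
    target_edges = round(spec.planted_module_size * spec.module_internal_degree / 2)
    need = target_edges - graph.subgraph(module).number_of_edges()
    if need > 0:
        absent = [
            (a, b)
            for i, a in enumerate(members)
            for b in members[i + 1:]
            if not graph.has_edge(a, b)
        ]
        chosen = rng.choice(len(absent), size=min(need, len(absent)), replace=False)
        for idx in chosen:
            graph.add_edge(*absent[idx])

    planted = frozenset(module)
    pvals: dict[str, float] = {}
    for g in nodes:
        if g in planted:
            pvals[g] = float(rng.uniform(0.0, spec.planted_p_max))
        else:
            pvals[g] = float(rng.uniform(0.0, 1.0))
    seed_subset = frozenset(
        rng.choice(sorted(planted), size=spec.seed_count(), replace=False).tolist()
    )
    return pvals, FixtureTruth(planted_gene_ids=planted, seed_subset=seed_subset)


def simulate_pathways(
    spec: FixtureSpec, truth: FixtureTruth, genes: Sequence[str] | None = None
):
    """Pathway collection with one disease pathway and controlled overlap.

    The disease pathway holds ~90% of the planted genes plus a few random
    extras. A handful of satellite pathways borrow ~30% of their genes from
    the disease pathway (kappa neighbors); the remaining pathways draw an
    ``overlap_rate`` fraction of their genes from a small shared pool so the
    background kappa-network density is tunable, and the rest uniformly.
    Returns ``(collection, truth)`` with pathway ids filled into the truth.
    """
    from .enrichment import GeneSetCollection

    rng = _rng(spec, "pathways")
    universe = sorted(genes) if genes is not None else gene_ids(spec)
    planted = sorted(truth.planted_gene_ids)
    background = sorted(set(universe) - truth.planted_gene_ids)

    lo, hi = spec.pathway_size_range
    sets: dict[str, tuple[str, frozenset]] = {}

    disease_id = "PWY000"
    n_core = max(1, int(round(DISEASE_PATHWAY_PURITY * len(planted))))
    core = rng.choice(planted, size=n_core, replace=False).tolist()
    n_extra = max(0, min(len(background), int(round(0.2 * n_core))))
    extra = rng.choice(background, size=n_extra, replace=False).tolist()
    sets[disease_id] = ("planted_disease_pathway", frozenset(core) | frozenset(extra))

    hub_pool = rng.choice(background, size=min(HUB_POOL_SIZE, len(background)),
                          replace=False).tolist()
    disease_genes = sorted(sets[disease_id][1])

    satellite_ids = []
    for i in range(1, spec.n_pathways):
        pid = f"PWY{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        members: set[str] = set()
        if i <= N_SATELLITE_PATHWAYS:
            satellite_ids.append(pid)
            n_borrow = min(len(disease_genes),
                           max(1, int(round(SATELLITE_BORROW_FRACTION * size))))
            members |= set(rng.choice(disease_genes, size=n_borrow, replace=False).tolist())
        else:
            n_hub = min(len(hub_pool), int(round(spec.overlap_rate * size)))
            if n_hub > 0:
                members |= set(rng.choice(hub_pool, size=n_hub, replace=False).tolist())
        while len(members) < size:
            members.add(background[int(rng.integers(len(background)))])
        sets[pid] = (f"synthetic_pathway_{i:03d}", frozenset(members))

    collection = GeneSetCollection(sets=sets, universe=frozenset(universe))
    truth = replace(
        truth,
        planted_pathway_ids=frozenset([disease_id, *satellite_ids]),
        disease_pathway_id=disease_id,
    )
    return collection, truth


def make_gene_models(spec: FixtureSpec, window: int = 50_000) -> list[GeneModel]:
    """Deterministic gene coordinates: genes laid out 1 Mb apart over 22
    chromosomes, far enough that flanking windows never overlap."""
    models = []
    for i, gid in enumerate(gene_ids(spec)):
        chrom = str((i % 22) + 1)
        slot = i // 22
        start = 1_000_000 * (slot + 1)
        end = start + 20_000
        models.append(GeneModel(gene_id=gid, chrom=chrom, start=start, end=end,
                                window=window))
    return models


def simulate_summary_stats(
    spec: FixtureSpec,
    truth: FixtureTruth,
    gene_models: Sequence[GeneModel],
) -> list[pd.DataFrame]:
    """One summary-statistic table per synthetic dataset.

    Per dataset each gene draws a fresh target p (planted genes from
    Uniform(0, planted_p_max), background from Uniform(0, 1)); one of its
    SNPs carries exactly that p and the rest draw Uniform(p, 1), so the
    gene-level minimum p equals the target. A random 5% of SNPs get a
    functional score fs ~ Uniform(0, 1).
    """
    rng = _rng(spec, "sumstats")
    by_id = {m.gene_id: m for m in gene_models}
    missing = [g for g in gene_ids(spec) if g not in by_id]
    if missing:
        raise ValueError(f"gene models missing for {missing[:5]}")

    alleles = np.array(list("ACGT"))
    datasets: list[pd.DataFrame] = []
    rs_counter = 1
    for _d in range(spec.n_datasets):
        rows = []
        for gid in gene_ids(spec):
            model = by_id[gid]
            if gid in truth.planted_gene_ids:
                p_gene = float(rng.uniform(0.0, spec.planted_p_max))
            else:
                p_gene = float(rng.uniform(0.0, 1.0))
            lo, hi = spec.snps_per_gene_range
            n_snps = int(rng.integers(lo, hi + 1))
            positions = rng.choice(
                np.arange(model.start + 1, model.end + 1), size=n_snps, replace=False
            )
            best = int(rng.integers(n_snps))
            for j in range(n_snps):
                p = p_gene if j == best else float(rng.uniform(p_gene, 1.0))
                ea, oa = rng.choice(alleles, size=2, replace=False)
                fs = float(rng.uniform(0.0, 1.0)) if rng.random() < FS_FRACTION else ""
                rows.append(
                    {
                        "chrom": model.chrom,
                        "pos": int(positions[j]),
                        "effect_allele": ea,
                        "other_allele": oa,
                        "p": p,
                        "rsid": f"rs{rs_counter}",
                        "fs": fs,
                    }
                )
                rs_counter += 1
        datasets.append(pd.DataFrame(rows))
    return datasets


@dataclass
class FixtureBundle:
    """Everything one synthetic study provides, generated in one call."""

    spec: FixtureSpec
    ppi: nx.Graph
    gene_pvalues: dict[str, float]
    truth: FixtureTruth
    collection: object  # GeneSetCollection
    gene_models: list[GeneModel]
    sumstats: list[pd.DataFrame] = field(default_factory=list)


def generate_bundle(spec: FixtureSpec, with_sumstats: bool = True) -> FixtureBundle:
    """Generate the full fixture set for one seed."""
    ppi = simulate_ppi(spec)
    pvals, truth = plant_module(ppi, spec)
    collection, truth = simulate_pathways(spec, truth)
    models = make_gene_models(spec)
    sumstats = simulate_summary_stats(spec, truth, models) if with_sumstats else []
    return FixtureBundle(
        spec=spec, ppi=ppi, gene_pvalues=pvals, truth=truth,
        collection=collection, gene_models=models, sumstats=sumstats,
    )


def write_bundle(bundle: FixtureBundle, out_dir) -> dict[str, str]:
    """Write a bundle as plain-text files; returns name -> path.

    Emits ppi.tsv, genes.bed, pathways.gmt, dataset1..N.tsv, gene_pvalues.tsv
    and truth.json. Byte-identical across runs with the same spec.
    """
    import json
    from pathlib import Path

    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    pio.write_ppi(bundle.ppi, out / "ppi.tsv")
    paths["ppi"] = str(out / "ppi.tsv")
    pio.write_bed(bundle.gene_models, out / "genes.bed")
    paths["genes"] = str(out / "genes.bed")
    pio.write_gmt(bundle.collection, out / "pathways.gmt")
    paths["pathways"] = str(out / "pathways.gmt")
    pd.DataFrame(
        {"gene_id": sorted(bundle.gene_pvalues),
         "p_gene": [bundle.gene_pvalues[g] for g in sorted(bundle.gene_pvalues)]}
    ).to_csv(out / "gene_pvalues.tsv", sep="\t", index=False)
    paths["gene_pvalues"] = str(out / "gene_pvalues.tsv")
    for i, df in enumerate(bundle.sumstats, start=1):
        p = out / f"dataset{i}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"dataset{i}"] = str(p)
    truth = {
        "planted_gene_ids": sorted(bundle.truth.planted_gene_ids),
        "seed_subset": sorted(bundle.truth.seed_subset),
        "planted_pathway_ids": sorted(bundle.truth.planted_pathway_ids),
        "disease_pathway_id": bundle.truth.disease_pathway_id,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    paths["truth"] = str(out / "truth.json")
    return paths
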