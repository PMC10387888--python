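"""End-to-end orchestration: summary statistics to pathway clusters and NMI.

``run_all`` executes preprocess -> gene scores -> cross-dataset combination ->
active subnetworks (-> optional DIAMOnD) -> per-module enrichment ->
consensus -> kappa pathway network -> pathway subnetworks / MCODE clusters ->
NMI comparisons, writing one TSV/JSON artifact per stage plus a manifest that
fully determines the run (parameters, seed, inputs, outputs; no timestamps,
so reruns are byte-identical).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .clustering import (
    McodeParams,
    PathwaySignificance,
    pathway_subnetworks,
    subdivide_large,
    DEFAULT_SIZE_THRESHOLD,
)
from .diamond import diamond_expand
from .enrichment import aggregate_dataset, consensus, enrich_module
from .gwas import (
    apply_functional_weighting,
    combine_across_datasets,
    filter_by_pvalue,
    map_snps_to_genes,
    read_summary_stats,
    score_genes,
)
from .pathway_network import build_pathway_network, DEFAULT_KAPPA_THRESHOLD
from .similarity import pairwise_nmi
from .subnetworks import (
    NodeZScores,
    calibrate,
    greedy_search,
    DEFAULT_MAX_SIZE,
    DEFAULT_MC_SAMPLES,
    DEFAULT_SCORE_CUTOFF,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the stage name is carried for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs and parameters of one run.

    Defaults are the conventional analysis parameters: SNP p-filter 0.05
    (strict), subnetwork score cutoff 3, kappa threshold 0.15, subnetwork
    subdivision threshold 50, alpha 0.05 with Benjamini-Hochberg.
    """

    datasets: dict[str, str] = field(default_factory=dict)  # label -> TSV path
    ppi: str = ""
    gene_bed: str = ""
    gmt: str = ""
    seeds_file: str | None = None
    columns: dict[str, str] = field(default_factory=dict)
    p_cutoff: float = 0.05
    gene_window: int = 50_000
    gene_statistic: str = "max_chi2"
    mc_samples: int = DEFAULT_MC_SAMPLES
    subnetwork_cutoff: float = DEFAULT_SCORE_CUTOFF
    max_subnetwork_size: int = DEFAULT_MAX_SIZE
    kappa_threshold: float = DEFAULT_KAPPA_THRESHOLD
    size_threshold: int = DEFAULT_SIZE_THRESHOLD
    alpha: float = 0.05
    correction: str = "benjamini_hochberg"
    diamond_n_add: int = 200
    include_combined: bool = True
    rng_seed: int = 17

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - abort names the stage
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("gene_scores")
def _gene_scores(config: PipelineConfig, out: Path):
    genes = pio.read_bed(config.gene_bed, window=config.gene_window)
    tables = {}
    for label, path in sorted(config.datasets.items()):
        records = read_summary_stats(path, config.columns or None)
        records = filter_by_pvalue(records, cutoff=config.p_cutoff)
        records = apply_functional_weighting(records)
        snps_by_gene = map_snps_to_genes(records, genes)
        table = score_genes(snps_by_gene, dataset_label=label,
                            kind=config.gene_statistic)
        pio.write_gene_scores(table, out / f"gene_scores_{label}.tsv")
        tables[label] = table
    return tables


@_stage("combine")
def _combine(tables: dict, out: Path):
    combined = combine_across_datasets(list(tables[k] for k in sorted(tables)))
    pio.write_gene_scores(combined, out / "gene_scores_combined.tsv")
    return combined


@_stage("subnetworks")
def _subnetworks(config: PipelineConfig, tables: dict, out: Path):
    ppi = pio.read_ppi(config.ppi)
    subnets_by_label = {}
    for i, label in enumerate(sorted(tables)):
        z = NodeZScores.from_pvalues(tables[label].pvalues())
        pool = len(set(z.entries) & set(ppi.nodes))
        if pool < 2:
            logger.warning("%s: fewer than 2 scored network nodes; skipping", label)
            subnets_by_label[label] = []
            continue
        cap = min(config.max_subnetwork_size, pool)
        calib = calibrate(
            {n: z[n] for n in set(z.entries) & set(ppi.nodes)},
            sizes=range(1, cap + 1),
            n_samples=config.mc_samples,
            seed=config.rng_seed + i,
        )
        subnets = greedy_search(
            ppi, z, calib,
            score_cutoff=config.subnetwork_cutoff, max_size=cap,
        )
        pio.write_subnetworks(subnets, out / f"subnetworks_{label}.tsv")
        subnets_by_label[label] = subnets
    return ppi, subnets_by_label


@_stage("diamond")
def _diamond(config: PipelineConfig, ppi, out: Path):
    seeds = pio.read_seed_file(config.seeds_file)
    result = diamond_expand(ppi, seeds, n_add=config.diamond_n_add)
    df = pd.DataFrame(
        [{"rank": a.rank, "node_id": a.node_id, "p_value": a.p_value,
          "ks": a.ks, "k": a.k} for a in result.additions]
    )
    df.to_csv(out / "diamond_additions.tsv", sep="\t", index=False)
    (out / "diamond_module.txt").write_text(
        "\n".join(sorted(result.module())) + "\n"
    )
    return result


@_stage("enrichment")
def _enrichment(config: PipelineConfig, subnets_by_label: dict, out: Path):
    collection = pio.read_gmt(config.gmt)
    per_dataset = {}
    for label, subnets in sorted(subnets_by_label.items()):
        per_module = [
            enrich_module(sn.node_ids, collection, alpha=config.alpha,
                          method=config.correction)
            for sn in subnets
        ]
        agg = aggregate_dataset(per_module) if per_module else {}
        rows = [
            {"pathway_id": pid, "p_adj": p, "rank": rank,
             "significant": p < config.alpha}
            for pid, (p, rank) in sorted(agg.items(), key=lambda kv: kv[1][1])
        ]
        pd.DataFrame(rows, columns=["pathway_id", "p_adj", "rank", "significant"]) \
            .to_csv(out / f"enrichment_{label}.tsv", sep="\t", index=False)
        per_dataset[label] = agg
    return collection, per_dataset


@_stage("consensus")
def _consensus(config: PipelineConfig, per_dataset: dict, out: Path):
    labels = [k for k in per_dataset if k != "combined"]
    if len(labels) < 2:
        logger.info("fewer than 2 datasets; skipping consensus")
        return pd.DataFrame()
    table = consensus({k: per_dataset[k] for k in labels}, alpha=config.alpha)
    table.to_csv(out / "consensus.tsv", sep="\t", index=False)
    return table


@_stage("pathway_network")
def _pathway_network(config: PipelineConfig, collection, out: Path):
    pnet = build_pathway_network(collection, threshold=config.kappa_threshold)
    rows = [
        {"pathway_a": a, "pathway_b": b, "kappa": d["kappa"]}
        for a, b, d in sorted(pnet.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "kappa"]) \
        .to_csv(out / "pathway_network.tsv", sep="\t", index=False)
    return pnet


@_stage("pathway_clusters")
def _pathway_clusters(config: PipelineConfig, pnet, per_dataset: dict, out: Path):
    # pathway-level significance: best (minimum) adjusted p over datasets
    labels = [k for k in per_dataset if k != "combined"]
    sig: dict[str, float] = {}
    for label in labels:
        for pid, (p, _rank) in per_dataset[label].items():
            p = max(p, 1e-300)
            if pid not in sig or p < sig[pid]:
                sig[pid] = p
    subnets = pathway_subnetworks(
        pnet, PathwaySignificance(entries=sig),
        cutoff=config.subnetwork_cutoff,
        mc_samples=config.mc_samples,
        seed=config.rng_seed + 101,
    )
    pio.write_subnetworks(subnets, out / "pathway_subnetworks.tsv")

    params = McodeParams()
    rows = []
    clusters_out = []
    cluster_id = 0
    for sn_idx, sn in enumerate(subnets, start=1):
        clusters = subdivide_large(sn, pnet, params,
                                   size_threshold=config.size_threshold)
        for cl in clusters:
            cluster_id += 1
            clusters_out.append((sn_idx, cl))
            rows.append(
                {
                    "cluster_id": f"PC{cluster_id:04d}",
                    "parent_subnetwork": f"SN{sn_idx:04d}",
                    "parent_s_A": sn.s_a,
                    "cluster_rank_in_parent": cl.rank,
                    "mcode_score": cl.mcode_score,
                    "n_pathways": len(cl.pathway_ids),
                    "members": ",".join(cl.sorted_members()),
                }
            )
    pd.DataFrame(
        rows,
        columns=["cluster_id", "parent_subnetwork", "parent_s_A",
                 "cluster_rank_in_parent", "mcode_score", "n_pathways", "members"],
    ).to_csv(out / "pathway_clusters.tsv", sep="\t", index=False)
    return subnets, clusters_out


@_stage("nmi")
def _nmi(config: PipelineConfig, subnets_by_label: dict, per_dataset: dict,
         collection, out: Path):
    labels = [k for k in sorted(subnets_by_label) if k != "combined"]
    if len(labels) < 2:
        return None, None
    module_sets = {
        lab: [set(sn.node_ids) for sn in subnets_by_label[lab]]
        for lab in labels
    }
    nmi_sub = None
    if all(module_sets[lab] for lab in labels):
        nmi_sub = pairwise_nmi(module_sets)
        nmi_sub.to_csv(out / "nmi_subnetworks.tsv", sep="\t")
    pathway_sets = {}
    for lab in labels:
        sig_paths = [pid for pid, (p, _r) in per_dataset[lab].items()
                     if p < config.alpha]
        pathway_sets[lab] = [set(collection.genes(pid)) for pid in sorted(sig_paths)]
    nmi_pw = None
    if all(pathway_sets[lab] for lab in labels):
        nmi_pw = pairwise_nmi(pathway_sets)
        nmi_pw.to_csv(out / "nmi_pathways.tsv", sep="\t")
    return nmi_sub, nmi_pw


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage; returns a dict of in-memory stage results.

    Artifacts and a manifest land in ``out_dir``. Any stage failure raises
    :class:`PipelineError` naming the stage; artifacts written before the
    failure are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key in ("ppi", "gene_bed", "gmt"):
        path = getattr(config, key)
        if not path or not Path(path).exists():
            raise PipelineError("inputs", f"missing input file for {key!r}: {path!r}")
    for label, path in config.datasets.items():
        if not Path(path).exists():
            raise PipelineError("inputs", f"missing dataset {label!r}: {path!r}")

    results: dict = {}
    tables = _gene_scores(config, out)
    results["gene_scores"] = tables
    if config.include_combined and len(tables) >= 2:
        tables = dict(tables)
        tables["combined"] = _combine(results["gene_scores"], out)
    ppi, subnets_by_label = _subnetworks(config, tables, out)
    results["subnetworks"] = subnets_by_label
    if config.seeds_file:
        results["diamond"] = _diamond(config, ppi, out)
    collection, per_dataset = _enrichment(config, subnets_by_label, out)
    results["enrichment"] = per_dataset
    results["consensus"] = _consensus(config, per_dataset, out)
    pnet = _pathway_network(config, collection, out)
    results["pathway_network"] = pnet
    pw_subnets, clusters = _pathway_clusters(config, pnet, per_dataset, out)
    results["pathway_subnetworks"] = pw_subnets
    results["pathway_clusters"] = clusters
    nmi_sub, nmi_pw = _nmi(config, subnets_by_label, per_dataset, collection, out)
    results["nmi_subnetworks"] = nmi_sub
    results["nmi_pathways"] = nmi_pw

    manifest = {
        "package": "pathnetgwas",
        "version": "0.1.0",
        "parameters": asdict(config),
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    results["manifest"] = manifest
    return results
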