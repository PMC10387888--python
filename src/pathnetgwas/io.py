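"""Readers and writers for the plain-text formats the toolkit exchanges:
TSV edge lists / SIF for PPI graphs, BED4 for gene models, GMT for pathway
collections, TSV for gene scores, subnetworks and seed lists."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .enrichment import GeneSetCollection
from .gwas import GeneModel, GeneScoreTable, DEFAULT_GENE_WINDOW
from .subnetworks import Subnetwork


def read_ppi(path) -> nx.Graph:
    """Two-column TSV edge list, or SIF (``node interaction node...``) when
    the file ends in .sif. Self-loops are dropped; the graph is simple."""
    path = Path(path)
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if path.suffix.lower() == ".sif":
                if len(parts) < 3:
                    continue
                src, targets = parts[0], parts[2:]
            else:
                if len(parts) < 2:
                    continue
                src, targets = parts[0], [parts[1]]
            for t in targets:
                if t != src:
                    g.add_edge(src, t)
    return g


def write_ppi(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_bed(path, window: int = DEFAULT_GENE_WINDOW) -> list[GeneModel]:
    """BED4 (chrom, start, end, gene_id); 0-based half-open intervals."""
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, gene_id = line.split("\t")[:4]
            models.append(GeneModel(gene_id=gene_id, chrom=chrom,
                                    start=int(start), end=int(end), window=window))
    return models


def write_bed(models: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_id}\n")


def read_gmt(path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """GMT: one pathway per line, tab-separated id, description, genes..."""
    sets: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pid, name, genes = parts[0], parts[1], parts[2:]
            sets[pid] = (name, frozenset(g for g in genes if g))
    return GeneSetCollection(
        sets=sets,
        universe=frozenset(universe) if universe is not None else frozenset(),
    )


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(collection.sets):
            name, genes = collection.sets[pid]
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


def write_gene_scores(table: GeneScoreTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_scores(path, dataset_label: str | None = None) -> GeneScoreTable:
    df = pd.read_csv(path, sep="\t")
    table = GeneScoreTable(dataset_label=dataset_label or Path(path).stem)
    for row in df.itertuples(index=False):
        table.entries[str(row.gene_id)] = (
            float(row.p_gene), int(row.n_snps), str(row.statistic_kind)
        )
    return table


def subnetworks_to_frame(subnets: Sequence[Subnetwork]) -> pd.DataFrame:
    rows = [
        {
            "subnetwork_id": f"SN{i:04d}",
            "seed": sn.seed_node,
            "k": sn.k,
            "z_A": sn.z_a,
            "s_A": sn.s_a,
            "members": ",".join(sn.sorted_members()),
        }
        for i, sn in enumerate(subnets, start=1)
    ]
    return pd.DataFrame(
        rows, columns=["subnetwork_id", "seed", "k", "z_A", "s_A", "members"]
    )


def write_subnetworks(subnets: Sequence[Subnetwork], path, as_json: bool = False) -> None:
    if as_json:
        payload = [
            {"seed": sn.seed_node, "k": sn.k, "z_A": sn.z_a, "s_A": sn.s_a,
             "members": sn.sorted_members()}
            for sn in subnets
        ]
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")
    else:
        subnetworks_to_frame(subnets).to_csv(path, sep="\t", index=False)


def read_seed_file(path) -> list[str]:
    """One node id per line; blank lines and # comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
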