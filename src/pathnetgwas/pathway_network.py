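"""Pathway co-membership network via Cohen's kappa.

Each pathway is a binary membership vector over the gene universe (the
gene-term matrix). For a pathway pair the 2x2 co-membership counters
(cn11, cn10, cn01, cn00) give observed agreement G = (cn11 + cn00) / total
and chance agreement

    C = [(cn11 + cn01)(cn11 + cn10) + (cn00 + cn10)(cn00 + cn01)] / total^2,

the standard product-of-margins form, and kappa K = (G - C) / (1 - C) with
K = 1 for the degenerate identical-margins case. Thresholding K (default 0.15,
inclusive) yields the pathway network; isolated pathways remain as nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .enrichment import GeneSetCollection

DEFAULT_KAPPA_THRESHOLD = 0.15


@dataclass
class MembershipMatrix:
    """Binary gene-term matrix: rows = genes, columns = pathways."""

    genes: list[str]
    pathways: list[str]
    cells: np.ndarray  # shape (n_genes, n_pathways), dtype bool

    def column(self, pathway_id: str) -> np.ndarray:
        return self.cells[:, self.pathways.index(pathway_id)]


@dataclass(frozen=True)
class KappaCounters:
    cn11: int
    cn10: int
    cn01: int
    cn00: int

    @property
    def total(self) -> int:
        return self.cn11 + self.cn10 + self.cn01 + self.cn00


@dataclass
class PathwayNetwork:
    """Pathways as nodes; kappa-weighted co-membership edges above threshold."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


def build_membership(collection: GeneSetCollection) -> MembershipMatrix:
    """Gene-term matrix over the union of all pathway genes (sorted labels)."""
    if not collection.sets:
        raise ValueError("collection must be non-empty")
    pathways = sorted(collection.sets)
    genes = sorted(set().union(*(collection.genes(p) for p in pathways)))
    gene_index = {g: i for i, g in enumerate(genes)}
    cells = np.zeros((len(genes), len(pathways)), dtype=bool)
    for j, pid in enumerate(pathways):
        for g in collection.genes(pid):
            cells[gene_index[g], j] = True
    return MembershipMatrix(genes=genes, pathways=pathways, cells=cells)


def kappa(
    membership_a: Sequence[bool] | np.ndarray,
    membership_b: Sequence[bool] | np.ndarray,
) -> tuple[KappaCounters, float]:
    """Cohen's kappa between two binary membership vectors."""
    a = np.asarray(membership_a, dtype=bool)
    b = np.asarray(membership_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    cn11 = int(np.sum(a & b))
    cn10 = int(np.sum(a & ~b))
    cn01 = int(np.sum(~a & b))
    cn00 = int(np.sum(~a & ~b))
    counters = KappaCounters(cn11=cn11, cn10=cn10, cn01=cn01, cn00=cn00)
    total = counters.total
    if total == 0:
        raise ValueError("empty membership vectors")
    g_obs = (cn11 + cn00) / total
    c_exp = ((cn11 + cn01) * (cn11 + cn10) + (cn00 + cn10) * (cn00 + cn01)) / total**2
    if c_exp == 1.0:
        return counters, 1.0
    return counters, (g_obs - c_exp) / (1.0 - c_exp)


def kappa_matrix(membership: MembershipMatrix) -> np.ndarray:
    """All-pairs kappa via matrix products (symmetric, unit diagonal)."""
    m = membership.cells.astype(np.int64)
    n_genes = m.shape[0]
    sizes = m.sum(axis=0)  # column sums = pathway sizes
    cn11 = m.T @ m
    cn10 = sizes[:, None] - cn11
    cn01 = sizes[None, :] - cn11
    cn00 = n_genes - cn11 - cn10 - cn01
    g_obs = (cn11 + cn00) / n_genes
    c_exp = ((cn11 + cn01) * (cn11 + cn10) + (cn00 + cn10) * (cn00 + cn01)) / n_genes**2
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(c_exp == 1.0, 1.0, (g_obs - c_exp) / (1.0 - c_exp))
    return k


def build_pathway_network(
    collection: GeneSetCollection,
    threshold: float = DEFAULT_KAPPA_THRESHOLD,
) -> PathwayNetwork:
    """Threshold the term-term kappa matrix into an undirected pathway graph.

    Edge (A, B) exists iff K_{A,B} >= threshold (inclusive); self-pairs are
    excluded and isolated pathways are kept as nodes.
    """
    if len(collection) < 2:
        raise ValueError("need at least two pathways")
    membership = build_membership(collection)
    k = kappa_matrix(membership)
    graph = nx.Graph()
    graph.add_nodes_from(membership.pathways)
    n = len(membership.pathways)
    for i in range(n):
        for j in range(i + 1, n):
            if k[i, j] >= threshold:
                graph.add_edge(
                    membership.pathways[i], membership.pathways[j],
                    kappa=float(k[i, j]),
                )
    return PathwayNetwork(graph=graph, threshold=threshold)
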