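"""Pathway subnetwork search and MCODE-style dense-cluster subdivision.

The active-subnetwork machinery runs unchanged on the kappa pathway network,
with enrichment p-values as node significance. Any subnetwork larger than 50
pathways is subdivided into densely connected clusters by a molecular-complex
detection (MCODE) scheme: vertices are weighted by local neighborhood density
(highest k-core number of the open neighborhood times that core's density),
then clusters grow outward from the heaviest unassigned seed, admitting
neighbors whose weight stays within ``node_score_cutoff`` of the seed's and
that connect to the growing cluster by at least ``k_core`` edges (so one
bridge edge cannot drag in a foreign dense region). An optional haircut trims
the cluster to its 2-core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .pathway_network import PathwayNetwork
from .subnetworks import (
    Calibration,
    NodeZScores,
    Subnetwork,
    calibrate,
    greedy_search,
)

logger = logging.getLogger(__name__)

DEFAULT_SIZE_THRESHOLD = 50


@dataclass(frozen=True)
class McodeParams:
    """MCODE tuning knobs at their conventional defaults."""

    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.node_score_cutoff < 1.0):
            raise ValueError("node_score_cutoff must be in [0,1)")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")


@dataclass
class PathwaySignificance:
    """Per-pathway corrected enrichment p-values (dataset-aggregated)."""

    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, p in self.entries.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(f"pathway {pid}: p must be in (0,1], got {p}")


@dataclass(frozen=True)
class PathwayCluster:
    """A dense pathway cluster with its MCODE score (density x size)."""

    pathway_ids: frozenset
    mcode_score: float
    rank: int
    seed: str | None = None

    def sorted_members(self) -> list[str]:
        return sorted(self.pathway_ids)


def pathway_subnetworks(
    pnet: PathwayNetwork,
    sig: PathwaySignificance | Mapping[str, float],
    calib: Calibration | None = None,
    cutoff: float = 3.0,
    max_size: int | None = None,
    mc_samples: int = 10_000,
    seed: int = 0,
) -> list[Subnetwork]:
    """Greedy active-subnetwork search on the pathway network.

    Pathways missing a significance value get p = 1 (no evidence), logged.
    The Monte-Carlo calibration is recomputed on the pathway significance pool
    unless a calibration is supplied.
    """
    entries = sig.entries if isinstance(sig, PathwaySignificance) else dict(sig)
    pvals: dict[str, float] = {}
    n_missing = 0
    for node in pnet.graph.nodes:
        if node in entries:
            pvals[node] = entries[node]
        else:
            pvals[node] = 1.0
            n_missing += 1
    if n_missing:
        logger.info("pathway_subnetworks: %d pathways without significance set to p=1",
                    n_missing)
    z = NodeZScores.from_pvalues(pvals)
    if calib is None:
        cap = len(pvals) if max_size is None else min(max_size, len(pvals))
        calib = calibrate(z, sizes=range(1, cap + 1), n_samples=mc_samples, seed=seed)
    return greedy_search(pnet.graph, z, calib, score_cutoff=cutoff, max_size=max_size)


def mcode_vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """Local-neighborhood-density vertex weights.

    weight(v) = (highest k-core number of the subgraph induced by v's open
    neighborhood) x (density of that highest k-core subgraph); 0 for isolated
    nodes and for neighborhoods without edges.
    """
    weights: dict[str, float] = {}
    for v in graph.nodes:
        nbrs = list(graph[v])
        if len(nbrs) < 2:
            weights[v] = 0.0
            continue
        sub = graph.subgraph(nbrs)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core = nx.core_number(sub)
        k_max = max(core.values())
        core_nodes = [n for n, c in core.items() if c >= k_max]
        core_sub = sub.subgraph(core_nodes)
        weights[v] = k_max * nx.density(core_sub)
    return weights


def _cluster_score(graph: nx.Graph, nodes: frozenset) -> float:
    sub = graph.subgraph(nodes)
    return nx.density(sub) * sub.number_of_nodes()


def mcode_clusters(
    graph: nx.Graph, params: McodeParams = McodeParams()
) -> list[PathwayCluster]:
    """Grow node-disjoint dense clusters from locally dense seeds.

    Seeds are taken in order of decreasing vertex weight (ties by node id).
    A neighbor joins the cluster when its weight >= seed weight x
    (1 - node_score_cutoff) and it has >= min(k_core, |cluster|) edges into
    the current members. Haircut trims the result to its 2-core. Nodes grown
    into a cluster are never reused, keeping clusters disjoint.
    """
    if graph.number_of_nodes() == 0:
        return []
    weights = mcode_vertex_weights(graph)
    unassigned = set(graph.nodes)
    order = sorted(graph.nodes, key=lambda n: (-weights[n], n))

    raw_clusters: list[tuple[frozenset, str]] = []
    for seed in order:
        if seed not in unassigned or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        while True:
            candidates = []
            for m in members:
                for nb in graph[m]:
                    if nb in unassigned and nb not in members:
                        candidates.append(nb)
            candidates = sorted(set(candidates), key=lambda n: (-weights[n], n))
            added = False
            for cand in candidates:
                if weights[cand] < threshold:
                    continue
                links = sum(1 for nb in graph[cand] if nb in members)
                if links >= min(params.k_core, len(members)):
                    members.add(cand)
                    added = True
                    break
            if not added:
                break
        grown = frozenset(members)
        unassigned -= grown  # consumed even if later trimmed away
        final = grown
        if params.haircut:
            final = frozenset(nx.k_core(graph.subgraph(grown), 2).nodes)
        if params.fluff:
            fluffed = set(final)
            for m in sorted(final):
                for nb in graph[m]:
                    if nb not in fluffed and weights.get(nb, 0.0) >= \
                            params.fluff_density * weights[seed]:
                        fluffed.add(nb)
            final = frozenset(fluffed)
        if len(final) >= 2:
            raw_clusters.append((final, seed))

    scored = [
        (_cluster_score(graph, nodes), nodes, seed) for nodes, seed in raw_clusters
    ]
    scored.sort(key=lambda t: (-t[0], sorted(t[1])))
    return [
        PathwayCluster(pathway_ids=nodes, mcode_score=float(s), rank=i, seed=seed)
        for i, (s, nodes, seed) in enumerate(scored, start=1)
    ]


def subdivide_large(
    subnet: Subnetwork,
    pnet: PathwayNetwork,
    params: McodeParams = McodeParams(),
    size_threshold: int = DEFAULT_SIZE_THRESHOLD,
) -> list[PathwayCluster]:
    """Subdivide a pathway subnetwork strictly larger than ``size_threshold``.

    At or below the threshold the subnetwork is returned unchanged as a single
    cluster (scored by density x size on the parent network); above it, MCODE
    runs on the induced subgraph.
    """
    missing = subnet.node_ids - set(pnet.graph.nodes)
    if missing:
        raise ValueError(f"subnetwork nodes missing from pathway network: {sorted(missing)[:5]}")
    if subnet.k <= size_threshold:
        return [
            PathwayCluster(
                pathway_ids=subnet.node_ids,
                mcode_score=_cluster_score(pnet.graph, subnet.node_ids),
                rank=1,
                seed=subnet.seed_node,
            )
        ]
    return mcode_clusters(pnet.graph.subgraph(subnet.node_ids).copy(), params)
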