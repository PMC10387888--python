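"""DIAMOnD-style disease-module detection (bottom-up network propagation).

Starting from known disease seed genes, the module grows one node per
iteration: every non-member with at least one link into the current module is
scored by the hypergeometric probability of having that many links by chance,

    p(k, ks) = C(s0, ks) C(N - s0, k - ks) / C(N, k),
    pvalue(k, ks) = sum_{ki = ks}^{k} p(k, ki),

where N is the network size, s0 the current module size, k the candidate's
degree and ks its links into the module. The node with the most significant
connectivity joins; p-values are recomputed against the grown module at every
step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from ._stats import hypergeom_logpmf, hypergeom_sf

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiamondQuery:
    """Connectivity-significance query for one candidate node."""

    N: int   # total nodes in the network
    s0: int  # current module size
    k: int   # candidate degree
    ks: int  # candidate links into the module

    def __post_init__(self) -> None:
        if not (0 <= self.ks <= min(self.k, self.s0)):
            raise ValueError(f"ks must satisfy 0 <= ks <= min(k, s0): {self}")
        if self.s0 > self.N:
            raise ValueError(f"s0 must be <= N: {self}")
        if not (0 <= self.k <= self.N - 1):
            raise ValueError(f"k must be in [0, N-1]: {self}")


@dataclass(frozen=True)
class DiamondAddition:
    rank: int
    node_id: str
    p_value: float
    ks: int
    k: int


@dataclass
class DiamondResult:
    """Ordered module additions plus the seed set."""

    seed_ids: frozenset
    additions: list[DiamondAddition] = field(default_factory=list)

    def module(self) -> frozenset:
        return self.seed_ids | {a.node_id for a in self.additions}


def connectivity_pmf(q: DiamondQuery) -> float:
    """Hypergeometric point mass p(k, ks), computed in log space."""
    return float(np.exp(hypergeom_logpmf(q.ks, q.N, q.s0, q.k)))


def connectivity_pvalue(q: DiamondQuery) -> float:
    """Upper-tail sum of the pmf from ks to k (support-truncated)."""
    return hypergeom_sf(q.ks, q.N, q.s0, q.k)


def _batch_pvalues(N: int, s0: int, ks: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Vectorized connectivity p-values for one iteration's candidate set."""
    out = np.empty(ks.size, dtype=float)
    for i in range(ks.size):
        hi = min(int(k[i]), s0)
        xs = np.arange(int(ks[i]), hi + 1)
        if xs.size == 0:
            out[i] = 0.0
            continue
        out[i] = min(1.0, float(np.exp(logsumexp(hypergeom_logpmf(xs, N, s0, int(k[i]))))))
    return out


def diamond_expand(network: nx.Graph, seeds: Iterable[str], n_add: int) -> DiamondResult:
    """Iteratively add the node with the most significant module connectivity.

    Candidates are non-members with >= 1 edge into the current module. Ties in
    minimum p-value are broken by higher ks, then lexicographic node id. Stops
    early (with a warning) if the candidate set empties before ``n_add``
    additions.
    """
    seeds = frozenset(seeds)
    missing = seeds - set(network.nodes)
    if missing:
        raise ValueError(f"seeds not in network: {sorted(missing)[:5]}")
    if n_add < 1:
        raise ValueError("n_add must be >= 1")

    N = network.number_of_nodes()
    degree = dict(network.degree())
    module = set(seeds)
    # links into the module, maintained incrementally
    ks_count: dict[str, int] = {}
    for s in seeds:
        for nb in network[s]:
            if nb not in module:
                ks_count[nb] = ks_count.get(nb, 0) + 1

    result = DiamondResult(seed_ids=seeds)
    for rank in range(1, n_add + 1):
        if not ks_count:
            logger.warning(
                "diamond_expand: no candidates left after %d additions", rank - 1
            )
            break
        cands = sorted(ks_count)
        ks_arr = np.array([ks_count[c] for c in cands], dtype=np.int64)
        k_arr = np.array([degree[c] for c in cands], dtype=np.int64)
        pvals = _batch_pvalues(N, len(module), ks_arr, k_arr)
        order = sorted(
            range(len(cands)), key=lambda i: (pvals[i], -ks_arr[i], cands[i])
        )
        best = order[0]
        node = cands[best]
        result.additions.append(
            DiamondAddition(
                rank=rank, node_id=node, p_value=float(pvals[best]),
                ks=int(ks_arr[best]), k=int(k_arr[best]),
            )
        )
        module.add(node)
        del ks_count[node]
        for nb in network[node]:
            if nb not in module:
                ks_count[nb] = ks_count.get(nb, 0) + 1
    return result
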