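"""Active-subnetwork identification (top-down search).

Node p-values become z-scores z_i = Phi^-1(1 - p_i); a candidate subnetwork A
with k nodes is scored z_A = (1/sqrt(k)) * sum_i z_i, then calibrated against a
Monte-Carlo null of random size-k node sets: s_A = (z_A - mu_k) / sigma_k.
A greedy hill-climb from every seed node grows the subnetwork by the neighbor
whose inclusion maximizes s_A, stopping at the first non-improving step.
Subnetworks with s_A >= 3 are reported, matching the conventional cutoff for
biologically meaningful modules.

The same machinery scores protein subnetworks on a PPI graph and pathway
subnetworks on a kappa co-membership graph.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import ndtri

logger = logging.getLogger(__name__)

P_LO = 1e-300
P_HI = 1.0 - 1e-16
SIGMA_FLOOR = 1e-8
DEFAULT_SCORE_CUTOFF = 3.0
DEFAULT_MAX_SIZE = 300
DEFAULT_MC_SAMPLES = 10_000


def p_to_z(p):
    """z = Phi^-1(1 - p), computed as -Phi^-1(p) for precision at tiny p.

    Inputs are clamped to [1e-300, 1 - 1e-16], so p = 1 maps to a large
    negative but finite z. Strictly decreasing in p. Accepts scalars or arrays.
    """
    arr = np.clip(np.asarray(p, dtype=float), P_LO, P_HI)
    z = -ndtri(arr)
    return float(z) if np.isscalar(p) or np.ndim(p) == 0 else z


@dataclass
class NodeZScores:
    """Per-node z-scores derived from p-values."""

    entries: dict[str, float]

    @classmethod
    def from_pvalues(cls, pvals: Mapping[str, float]) -> "NodeZScores":
        keys = list(pvals)
        zs = p_to_z(np.array([pvals[k] for k in keys], dtype=float))
        return cls(entries=dict(zip(keys, np.atleast_1d(zs).tolist())))

    def __getitem__(self, node: str) -> float:
        return self.entries[node]

    def __contains__(self, node: str) -> bool:
        return node in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def aggregate_z(z_values: Sequence[float]) -> float:
    """z_A = (sum of node z-scores) / sqrt(k)."""
    zs = np.asarray(z_values, dtype=float)
    if zs.size == 0:
        raise ValueError("aggregate_z requires a non-empty list")
    return float(zs.sum() / np.sqrt(zs.size))


@dataclass
class Calibration:
    """Monte-Carlo null moments of z_A per subnetwork size k."""

    entries: dict[int, tuple[float, float, int]]  # k -> (mu_k, sigma_k, n_samples)
    rng_seed: int

    def mu(self, k: int) -> float:
        return self.entries[k][0]

    def sigma(self, k: int) -> float:
        return self.entries[k][1]

    def max_size(self) -> int:
        return max(self.entries)

    def __contains__(self, k: int) -> bool:
        return k in self.entries


def _sample_index_matrix(rng: np.random.Generator, n_pool: int, max_k: int,
                         n_samples: int) -> np.ndarray:
    """(n_samples, max_k) indices; each row a uniform without-replacement draw
    whose every prefix is itself a uniform subset of its size.

    Small pools: random-key argsort (full permutation prefix). Large pools with
    max_k << n_pool: draw with replacement and redraw the few rows containing
    duplicates (collision probability ~ max_k^2 / 2 n_pool).
    """
    if n_pool <= 4096 or max_k * max_k * 10 > n_pool:
        out = np.empty((n_samples, max_k), dtype=np.int64)
        chunk = max(1, int(2e7) // max(n_pool, 1))
        for lo in range(0, n_samples, chunk):
            hi = min(lo + chunk, n_samples)
            keys = rng.random((hi - lo, n_pool))
            out[lo:hi] = np.argsort(keys, axis=1)[:, :max_k]
        return out
    idx = rng.integers(0, n_pool, size=(n_samples, max_k))
    for _ in range(100):
        sorted_rows = np.sort(idx, axis=1)
        bad = np.any(sorted_rows[:, 1:] == sorted_rows[:, :-1], axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, n_pool, size=(int(bad.sum()), max_k))
    raise RuntimeError("rejection sampling failed to produce distinct indices")


def calibrate(
    z_pool: "NodeZScores | Mapping[str, float] | Sequence[float]",
    sizes: Iterable[int],
    n_samples: int = DEFAULT_MC_SAMPLES,
    seed: int = 0,
) -> Calibration:
    """Estimate (mu_k, sigma_k) of z_A under random size-k node sets.

    For each k, ``n_samples`` node sets are drawn uniformly without replacement
    from the pool (topology is ignored: the null is over node scores, which
    keeps the calibration cheap and conservative). Reproducible given ``seed``.
    """
    if isinstance(z_pool, NodeZScores):
        values = np.array(sorted(z_pool.entries.values()), dtype=float)
    elif isinstance(z_pool, Mapping):
        values = np.array([z_pool[k] for k in sorted(z_pool)], dtype=float)
    else:
        values = np.asarray(z_pool, dtype=float)
    sizes = sorted(set(int(k) for k in sizes))
    if not sizes or sizes[0] < 1:
        raise ValueError("sizes must be positive integers")
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    max_k = sizes[-1]
    if max_k > values.size:
        raise ValueError(f"size {max_k} exceeds pool size {values.size}")

    rng = np.random.default_rng(seed)
    idx = _sample_index_matrix(rng, values.size, max_k, n_samples)
    cum = np.cumsum(values[idx], axis=1)
    entries: dict[int, tuple[float, float, int]] = {}
    for k in sizes:
        z_a = cum[:, k - 1] / np.sqrt(k)
        mu = float(z_a.mean())
        sigma = float(max(z_a.std(ddof=1), SIGMA_FLOOR))
        entries[k] = (mu, sigma, n_samples)
    return Calibration(entries=entries, rng_seed=seed)


@dataclass(frozen=True)
class Subnetwork:
    """A connected node set with aggregate score z_A and calibrated score s_A."""

    node_ids: frozenset
    k: int
    z_a: float
    s_a: float
    seed_node: str | None = None

    def sorted_members(self) -> list[str]:
        return sorted(self.node_ids)


def score(
    subnet_nodes: Iterable[str], z: NodeZScores, calib: Calibration,
    seed_node: str | None = None,
) -> Subnetwork:
    """Score a node set: s_A = (z_A - mu_k) / sigma_k."""
    nodes = frozenset(subnet_nodes)
    k = len(nodes)
    if k not in calib:
        raise KeyError(f"no calibration entry for subnetwork size {k}")
    z_a = aggregate_z([z[n] for n in nodes])
    s_a = (z_a - calib.mu(k)) / calib.sigma(k)
    return Subnetwork(node_ids=nodes, k=k, z_a=z_a, s_a=s_a, seed_node=seed_node)


def greedy_search(
    network: nx.Graph,
    z: NodeZScores,
    calib: Calibration,
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
    max_size: int | None = None,
    seeds: Iterable[str] | None = None,
) -> list[Subnetwork]:
    """Greedy active-subnetwork search, one hill-climb per seed node.

    From each seed, repeatedly add the neighboring node whose inclusion
    maximizes s_A (equivalently, the scored neighbor with the largest z, since
    mu and sigma are fixed at each size); stop when no addition increases s_A
    or ``max_size`` is reached. Unscored neighbors are excluded and logged.
    Duplicate node sets are collapsed; results with s_A >= ``score_cutoff``
    are returned sorted by s_A descending (ties by member list).
    """
    if any(network.has_edge(n, n) for n in network):
        raise ValueError("network must be simple (no self-loops)")
    cap = calib.max_size()
    if max_size is not None:
        cap = min(cap, max_size)

    scored = set(z.entries) & set(network.nodes)
    unscored = set(network.nodes) - scored
    if unscored:
        logger.info("greedy_search: %d unscored nodes excluded", len(unscored))
    if seeds is None:
        seed_list = sorted(scored)
    else:
        seed_list = sorted(set(seeds) & scored)

    best: dict[frozenset, Subnetwork] = {}
    for seed in seed_list:
        members = {seed}
        z_sum = z[seed]
        if 1 not in calib:
            raise KeyError("calibration must include size 1")
        s_cur = (z_sum - calib.mu(1)) / calib.sigma(1)
        # max-heap of candidate neighbors keyed by (-z, node id)
        heap: list[tuple[float, str]] = []
        in_heap: set[str] = set()
        for nb in network[seed]:
            if nb in scored:
                heapq.heappush(heap, (-z[nb], nb))
                in_heap.add(nb)
        while len(members) < cap and (len(members) + 1) in calib and heap:
            z_c, cand = heap[0]
            z_c = -z_c
            k_new = len(members) + 1
            s_new = ((z_sum + z_c) / np.sqrt(k_new) - calib.mu(k_new)) / calib.sigma(k_new)
            if s_new <= s_cur:
                break
            heapq.heappop(heap)
            members.add(cand)
            z_sum += z_c
            s_cur = s_new
            for nb in network[cand]:
                if nb in scored and nb not in members and nb not in in_heap:
                    heapq.heappush(heap, (-z[nb], nb))
                    in_heap.add(nb)
        key = frozenset(members)
        if key not in best:
            k = len(members)
            best[key] = Subnetwork(
                node_ids=key, k=k, z_a=float(z_sum / np.sqrt(k)),
                s_a=float(s_cur), seed_node=seed,
            )

    results = [sn for sn in best.values() if sn.s_a >= score_cutoff]
    results.sort(key=lambda sn: (-sn.s_a, sn.sorted_members()))
    return results
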