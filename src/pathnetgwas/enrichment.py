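"""Hypergeometric over-representation analysis against pathway gene sets.

With f genes in the annotation universe, g in the pathway, d in the query set
(after intersecting with the universe) and k shared, the enrichment p-value is
the upper hypergeometric tail

    P = sum_{i = k}^{min(g, d)} C(g, i) C(f - g, d - i) / C(f, d),

corrected for multiple testing by Bonferroni or Benjamini-Hochberg. A pathway
is called significant when its corrected p is below alpha (default 0.05).
Cross-dataset consensus keeps pathways significant in every dataset, where a
dataset's pathway-level p is the minimum adjusted p over that dataset's
modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import hypergeom_sf

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class GeneSetCollection:
    """A pathway collection: id -> (name, gene set), plus a gene universe.

    The universe defaults to the union of all pathway genes (the annotation
    universe). Pathway genes outside a custom universe are dropped with a log
    message; empty pathways are rejected.
    """

    sets: dict[str, tuple[str, frozenset]]
    universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(*(g for _, g in self.sets.values())) \
                if self.sets else frozenset()
        cleaned: dict[str, tuple[str, frozenset]] = {}
        for pid, (name, genes) in self.sets.items():
            kept = frozenset(genes) & self.universe
            if len(kept) < len(genes):
                logger.info("pathway %s: %d genes outside universe dropped",
                            pid, len(genes) - len(kept))
            if not kept:
                raise ValueError(f"pathway {pid} is empty (after universe restriction)")
            cleaned[pid] = (name, kept)
        self.sets = cleaned

    def genes(self, pathway_id: str) -> frozenset:
        return self.sets[pathway_id][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    f: int
    g: int
    d: int
    k_overlap: int
    p_raw: float
    p_adj: float
    rank: int
    significant: bool


def enrich_p(f: int, g: int, d: int, k: int) -> float:
    """Upper-tail hypergeometric enrichment p-value."""
    if not (0 <= g <= f and 0 <= d <= f):
        raise ValueError(f"need g <= f and d <= f; got f={f}, g={g}, d={d}")
    if not (0 <= k <= min(g, d)):
        raise ValueError(f"need 0 <= k <= min(g, d); got k={k}, g={g}, d={d}")
    return hypergeom_sf(k, f, g, d)


def adjust(p_values: Sequence[float], method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-testing correction, order preserved relative to the input."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        return ps.copy()
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must be in (0,1]")
    if method == "bonferroni":
        return np.minimum(1.0, ps * ps.size)
    if method == "benjamini_hochberg":
        return stats.false_discovery_control(ps, method="bh")
    raise ValueError(f"unknown correction method: {method!r}")


def enrich_module(
    genes: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    method: str = "benjamini_hochberg",
) -> list[EnrichmentResult]:
    """Test one gene set against every pathway in the collection.

    The query is intersected with the universe before d is computed;
    out-of-universe genes are dropped and logged. Results are sorted by
    (p_adj, p_raw, pathway_id) and ranked from 1.
    """
    query = set(genes)
    in_universe = query & collection.universe
    if len(in_universe) < len(query):
        logger.info("%d query genes outside universe dropped",
                    len(query) - len(in_universe))
    if not in_universe:
        logger.warning("query is disjoint from the universe; nothing can enrich")
    f = len(collection.universe)
    d = len(in_universe)

    pids = sorted(collection.sets)
    raws = []
    overlaps = []
    for pid in pids:
        pw_genes = collection.genes(pid)
        k = len(pw_genes & in_universe)
        overlaps.append(k)
        raws.append(enrich_p(f, len(pw_genes), d, k))
    adjs = adjust(raws, method=method)

    order = sorted(range(len(pids)), key=lambda i: (adjs[i], raws[i], pids[i]))
    results = []
    for rank, i in enumerate(order, start=1):
        pid = pids[i]
        results.append(
            EnrichmentResult(
                pathway_id=pid, f=f, g=len(collection.genes(pid)), d=d,
                k_overlap=overlaps[i], p_raw=float(raws[i]),
                p_adj=float(adjs[i]), rank=rank,
                significant=bool(adjs[i] < alpha),
            )
        )
    return results


def aggregate_dataset(
    per_module: Sequence[Sequence[EnrichmentResult]],
) -> dict[str, tuple[float, int]]:
    """Collapse per-module enrichment into one pathway -> (p_adj, rank) map.

    A pathway's dataset-level adjusted p is the minimum over the dataset's
    modules; its rank is recomputed from the aggregated p-values.
    """
    best_p: dict[str, float] = {}
    for results in per_module:
        for r in results:
            if r.pathway_id not in best_p or r.p_adj < best_p[r.pathway_id]:
                best_p[r.pathway_id] = r.p_adj
    ranked = sorted(best_p.items(), key=lambda kv: (kv[1], kv[0]))
    return {pid: (p, rank) for rank, (pid, p) in enumerate(ranked, start=1)}


def consensus(
    per_dataset: Mapping[str, Mapping[str, tuple[float, int]]],
    alpha: float = DEFAULT_ALPHA,
    min_datasets: int | None = None,
) -> pd.DataFrame:
    """Pathways significant across datasets.

    ``per_dataset`` maps dataset label -> {pathway -> (p_adj, rank)} (the
    output of :func:`aggregate_dataset`). Strict consensus (the default)
    requires significance (p_adj < alpha) in every dataset; ``min_datasets``
    relaxes this to at-least-k-of-n. Returns a DataFrame sorted by the number
    of supporting datasets (desc) then best p_adj.
    """
    if len(per_dataset) < 2:
        raise ValueError("consensus requires at least two datasets")
    labels = sorted(per_dataset)
    need = len(labels) if min_datasets is None else min_datasets

    all_pids = sorted(set().union(*(set(m) for m in per_dataset.values())))
    rows = []
    for pid in all_pids:
        n_sig = 0
        row: dict = {"pathway_id": pid}
        best = np.inf
        for lab in labels:
            entry = per_dataset[lab].get(pid)
            if entry is None:
                row[f"p_adj_{lab}"] = np.nan
                row[f"rank_{lab}"] = np.nan
                continue
            p, rank = entry
            row[f"p_adj_{lab}"] = p
            row[f"rank_{lab}"] = rank
            best = min(best, p)
            if p < alpha:
                n_sig += 1
        row["n_significant"] = n_sig
        row["best_p_adj"] = best
        if n_sig >= need:
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["n_significant", "best_p_adj", "pathway_id"],
            ascending=[False, True, True],
        ).reset_index(drop=True)
    return df
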