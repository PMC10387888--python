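"""Cross-dataset module comparison via normalized mutual information.

Two module sets U = {U_1..U_R} and V = {V_1..V_S} (subnetwork gene sets or
enriched-pathway gene sets from two datasets) are compared through the
contingency table of shared-gene counts n_ij = |U_i intersect V_j| with
margins a_i, b_j and grand total N. Entropies and mutual information use
natural logs (the base cancels in the normalized ratio):

    H(U) = -sum_i (a_i/N) log(a_i/N)
    I(U,V) = sum_ij (n_ij/N) log( (n_ij/N) / (a_i b_j / N^2) )
    NMI_SUM = 2 I(U,V) / (H(U) + H(V))  in [0, 1].

Module sets may overlap (the margins are computed from the table itself, so
the joint distribution stays well-formed); 0 log 0 = 0; the degenerate
single-block case H(U)+H(V) = 0 is defined as NMI = 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Shared-gene counts between two module sets, with margins."""

    row_labels: list[str]
    col_labels: list[str]
    n: np.ndarray  # shape (R, S) integer counts

    @property
    def a(self) -> np.ndarray:
        return self.n.sum(axis=1)

    @property
    def b(self) -> np.ndarray:
        return self.n.sum(axis=0)

    @property
    def N(self) -> int:
        return int(self.n.sum())


@dataclass(frozen=True)
class NmiResult:
    h_u: float
    h_v: float
    i_uv: float
    nmi_sum: float


def contingency(
    modules_u: Sequence[set], modules_v: Sequence[set],
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> ContingencyTable:
    """n_ij = |U_i intersect V_j| for every module pair."""
    if not modules_u or not modules_v:
        raise ValueError("both module lists must be non-empty")
    rows = list(row_labels) if row_labels is not None else \
        [f"U{i + 1}" for i in range(len(modules_u))]
    cols = list(col_labels) if col_labels is not None else \
        [f"V{j + 1}" for j in range(len(modules_v))]
    n = np.zeros((len(modules_u), len(modules_v)), dtype=np.int64)
    for i, u in enumerate(modules_u):
        u = set(u)
        for j, v in enumerate(modules_v):
            n[i, j] = len(u & set(v))
    return ContingencyTable(row_labels=rows, col_labels=cols, n=n)


def nmi(table: ContingencyTable) -> NmiResult:
    """Entropies, mutual information and NMI_SUM from a contingency table."""
    N = table.N
    if N == 0:
        raise ValueError(
            "contingency table has no shared genes (N=0); "
            "report 'no overlap' instead of an NMI value"
        )
    a = table.a / N
    b = table.b / N
    h_u = float(-np.sum(a[a > 0] * np.log(a[a > 0])))
    h_v = float(-np.sum(b[b > 0] * np.log(b[b > 0])))

    p = table.n / N
    mask = p > 0
    outer = np.outer(a, b)
    i_uv = float(np.sum(p[mask] * np.log(p[mask] / outer[mask])))

    if h_u + h_v == 0.0:
        logger.info("degenerate single-block comparison; NMI defined as 1")
        nmi_sum = 1.0
    else:
        nmi_sum = 2.0 * i_uv / (h_u + h_v)
    nmi_sum = float(min(1.0, max(0.0, nmi_sum)))
    return NmiResult(h_u=h_u, h_v=h_v, i_uv=i_uv, nmi_sum=nmi_sum)


def pairwise_nmi(sets_by_dataset: Mapping[str, Sequence[set]]) -> pd.DataFrame:
    """Symmetric NMI_SUM matrix over all dataset pairs.

    The diagonal is reported as 1.0 by construction (a module set compared
    with itself); display conventions often whiten it.
    """
    if len(sets_by_dataset) < 2:
        raise ValueError("need at least two datasets")
    labels = sorted(sets_by_dataset)
    mat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels,
                       columns=labels)
    for i, u_lab in enumerate(labels):
        for v_lab in labels[i + 1:]:
            table = contingency(sets_by_dataset[u_lab], sets_by_dataset[v_lab])
            if table.N == 0:
                value = 0.0
                logger.warning("no shared genes between %s and %s", u_lab, v_lab)
            else:
                value = nmi(table).nmi_sum
            mat.loc[u_lab, v_lab] = value
            mat.loc[v_lab, u_lab] = value
    return mat


def target_pathway_ranks(
    enrichment: Sequence[EnrichmentResult], targets: set[str]
) -> list[tuple[str, float, float]]:
    """Ranks and adjusted p-values of target pathways in an enrichment list.

    Targets absent from the results are reported with rank = inf and p = 1.
    Sorted by rank ascending (missing targets last, by id).
    """
    by_id = {r.pathway_id: r for r in enrichment}
    rows: list[tuple[str, float, float]] = []
    for t in sorted(targets):
        if t in by_id:
            rows.append((t, float(by_id[t].rank), by_id[t].p_adj))
        else:
            rows.append((t, math.inf, 1.0))
    rows.sort(key=lambda r: (r[1], r[0]))
    return rows
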