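"""Shared low-level statistics: log-space hypergeometric masses and tails.

Both the DIAMOnD connectivity test and the over-representation test reduce to
an upper-tail hypergeometric probability; they are kept in one place so the
exhaustive small-population oracle in the tests covers both callers.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = ["log_binom", "hypergeom_logpmf", "hypergeom_sf"]


def log_binom(n, k):
    """log C(n, k), vectorized; -inf where k < 0 or k > n."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    bad = (k < 0) | (k > n)
    return np.where(bad, -np.inf, out)


def hypergeom_logpmf(x, total, n_success, n_draw):
    """log P(X = x) for X ~ Hypergeom(total, n_success, n_draw).

    P(X=x) = C(n_success, x) C(total - n_success, n_draw - x) / C(total, n_draw)
    """
    return (
        log_binom(n_success, x)
        + log_binom(total - n_success, np.asarray(n_draw, dtype=float) - x)
        - log_binom(total, n_draw)
    )


def hypergeom_sf(x_min: int, total: int, n_success: int, n_draw: int) -> float:
    """Upper tail P(X >= x_min), summed in log space.

    Returns exactly 1.0 when x_min is at or below the lower support bound.
    """
    lo = max(0, n_draw - (total - n_success))
    hi = min(n_draw, n_success)
    if x_min <= lo:
        return 1.0
    if x_min > hi:
        return 0.0
    xs = np.arange(x_min, hi + 1)
    logp = hypergeom_logpmf(xs, total, n_success, n_draw)
    return float(min(1.0, np.exp(logsumexp(logp))))
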