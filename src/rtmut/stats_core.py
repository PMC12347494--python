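"""Shared statistical primitives.

- Benjamini-Hochberg step-up FDR adjustment.
- Two-sided Mann-Whitney U with an exact permutation branch for small
  groups (full enumeration of group assignments, mid-ranks for ties) and
  a tie-corrected normal approximation with continuity correction beyond.
- Geometric-mean combination of replicate p-values.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

#: Largest number of group assignments the exact branch will enumerate.
MAX_EXACT_ENUMERATIONS = 50_000


def bh_correct(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


class MannWhitneyResult(NamedTuple):
    u: float  # U statistic of the first group
    pvalue: float
    method: str  # "exact" or "asymptotic"


def _u_statistic(ranks: np.ndarray, n: int) -> float:
    return float(ranks[:n].sum() - n * (n + 1) / 2)


def mann_whitney_two_sided(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    The exact branch enumerates every assignment of the pooled values to
    the two groups (mid-ranks handle ties) and counts assignments whose U
    deviates from the null mean at least as much as observed. It is used
    whenever C(n+m, min(n, m)) <= ``MAX_EXACT_ENUMERATIONS``; otherwise the
    tie-corrected normal approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = x.size, y.size
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    n_assignments = comb(n + m, min(n, m))
    if method == "auto":
        method = "exact" if n_assignments <= MAX_EXACT_ENUMERATIONS else "asymptotic"
    if method == "asymptotic":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return MannWhitneyResult(float(res.statistic), min(float(res.pvalue), 1.0), "asymptotic")

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, n)
    n_le = 0
    n_ge = 0
    total = 0
    base = n * (n + 1) / 2
    for idx in combinations(range(n + m), n):
        u = ranks.take(idx).sum() - base
        n_le += u <= u_obs + 1e-9
        n_ge += u >= u_obs - 1e-9
        total += 1
    # two-sided: doubled smaller tail (both tails include the observed value)
    p = min(1.0, 2 * min(n_le, n_ge) / total)
    return MannWhitneyResult(u_obs, p, "exact")


def geometric_mean_p(pvals: Sequence[float]) -> float:
    """exp(mean(log p)) over strictly positive p-values in (0, 1]."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.exp(np.mean(np.log(p))))
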