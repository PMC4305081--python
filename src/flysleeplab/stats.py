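"""Nonparametric rank statistics and summary conventions.

The tests here are implemented from first principles so that small-sample
behavior is exactly specified: the Mann-Whitney U test uses a full exact
null distribution (dynamic-programming count of rank configurations) for
small, tie-free samples and a tie-corrected, continuity-corrected normal
approximation otherwise; Kruskal-Wallis uses the tie-corrected H statistic
against a chi-square reference.

The ``conservative_p`` convention — report only the numerically greatest
p value across the pairwise control comparisons — is the multiple-control
reporting rule used throughout the sleep and imaging analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import chdtrc

__all__ = [
    "RankTestResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "conservative_p",
    "mean_sem",
]

# Largest min(n, m) for which the exact Mann-Whitney null distribution is
# enumerated. Above this (or in the presence of ties) the normal
# approximation with tie and continuity corrections is used.
EXACT_THRESHOLD = 8


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of a rank test.

    statistic is U (Mann-Whitney, for the first sample) or H
    (Kruskal-Wallis). method records which p-value path was taken.
    """

    statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx" | "chi2" | "degenerate"
    n_per_group: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value out of (0, 1]: {self.p_value}")


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..N with ties sharing the average (mid) rank."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    n = len(pooled)
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _exact_u_counts(n: int, m: int) -> np.ndarray:
    """Null distribution of U for sample sizes (n, m) without ties.

    Returns counts[u] = number of the C(n+m, n) rank configurations with
    U statistic u, for u in 0..n*m, via the standard recurrence
    c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u).
    """
    # table[i][j] is the count vector over u for sizes (i, j)
    prev = [np.ones(1, dtype=float) for _ in range(m + 1)]
    for i in range(1, n + 1):
        cur: list[np.ndarray] = [np.ones(1, dtype=float)]
        for j in range(1, m + 1):
            c = np.zeros(i * j + 1, dtype=float)
            a = prev[j]  # sizes (i-1, j): shift by j
            c[j : j + len(a)] += a
            b = cur[j - 1]  # sizes (i, j-1): no shift
            c[: len(b)] += b
            cur.append(c)
        prev = cur
    return prev[m]


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    *,
    exact_threshold: int = EXACT_THRESHOLD,
    continuity: bool = True,
) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    U is reported for the first sample (number of (x, y) pairs with
    x > y, counting ties as 1/2). Exact p by full enumeration of the null
    distribution when min(n, m) <= exact_threshold and there are no ties;
    otherwise a normal approximation with tie correction and (by
    default) continuity correction. Identical pooled values give p = 1
    by convention. Without the continuity correction the approximate p
    coincides with a 2-group Kruskal-Wallis test (H = z^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankTestResult(n * m / 2.0, 1.0, "degenerate", (n, m))

    ranks = _midranks(pooled)
    r1 = float(np.sum(ranks[:n]))
    u1 = r1 - n * (n + 1) / 2.0
    u_min = min(u1, n * m - u1)

    has_ties = len(np.unique(pooled)) < pooled.size
    if not has_ties and min(n, m) <= exact_threshold:
        counts = _exact_u_counts(n, m)
        total = counts.sum()
        # distribution symmetric about nm/2: two-sided p doubles one tail
        p = 2.0 * counts[: int(round(u_min)) + 1].sum() / total
        return RankTestResult(u1, min(1.0, p), "exact", (n, m))

    mu = n * m / 2.0
    nn = n + m
    tie = _tie_term(pooled)
    var = n * m / 12.0 * ((nn + 1) - tie / (nn * (nn - 1)))
    if var <= 0:
        return RankTestResult(u1, 1.0, "degenerate", (n, m))
    z = (abs(u1 - mu) - (0.5 if continuity else 0.0)) / math.sqrt(var)
    z = max(z, 0.0)
    p = math.erfc(z / math.sqrt(2.0))
    return RankTestResult(u1, min(1.0, p), "normal_approx", (n, m))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Kruskal-Wallis H test with tie correction.

    H = 12/(N(N+1)) * sum(R_j^2 / n_j) - 3(N+1), divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from chi-square with k - 1
    degrees of freedom.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    sizes = tuple(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    big_n = pooled.size
    if np.all(pooled == pooled[0]):
        return RankTestResult(0.0, 1.0, "degenerate", sizes)

    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        rj = float(np.sum(ranks[start : start + a.size]))
        h += rj * rj / a.size
        start += a.size
    h = 12.0 / (big_n * (big_n + 1)) * h - 3.0 * (big_n + 1)
    correction = 1.0 - _tie_term(pooled) / (big_n**3 - big_n)
    if correction <= 0:
        return RankTestResult(0.0, 1.0, "degenerate", sizes)
    h /= correction
    df = len(arrays) - 1
    p = float(chdtrc(df, max(h, 0.0)))
    return RankTestResult(h, min(1.0, max(p, np.nextafter(0, 1))), "chi2", sizes)


def conservative_p(pairwise_ps: Sequence[float]) -> float:
    """The most conservative (numerically greatest) of several p values."""
    ps = list(pairwise_ps)
    if not ps:
        raise ValueError("conservative_p requires at least one p value")
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p value out of (0, 1]: {p}")
    return max(ps)


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error of the mean (sample SD / sqrt(n)).

    SEM is NaN for n = 1. NaN inputs are excluded.
    """
    a = np.asarray(values, dtype=float)
    a = a[~np.isnan(a)]
    if a.size == 0:
        raise ValueError("mean_sem requires at least one finite value")
    mean = float(np.mean(a))
    if a.size == 1:
        return mean, float("nan")
    sem = float(np.std(a, ddof=1) / math.sqrt(a.size))
    return mean, sem
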