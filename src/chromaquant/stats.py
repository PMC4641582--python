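"""Nonparametric comparison of per-image statistics across levels.

The Friedman rank test (with mid-rank ties and the tie-corrected
chi-square approximation) tests whether a per-image statistic differs
across the K sensitivity levels.  All K(K-1)/2 level pairs are then
compared with the mean-rank z statistic

    z = (Rbar_i - Rbar_j) / sqrt(K(K+1) / (6N))

and two-sided normal p-values, adjusted with Holm's step-down procedure
and with Shaffer's static step-down procedure, which replaces Holm's
divisor m - i + 1 by the maximum number of pairwise hypotheses that can
simultaneously be true once i - 1 have been rejected (a number
constrained by the transitivity of equality among levels).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "FriedmanResult",
    "PosthocPair",
    "PosthocResult",
    "friedman",
    "pairwise_posthoc",
    "nonsignificant_pairs",
    "shaffer_true_counts",
    "shaffer_divisors",
]


@dataclass
class FriedmanResult:
    statistic: float
    p_value: float
    n_used: int
    n_dropped: int
    k: int


@dataclass
class PosthocPair:
    level_i: int
    level_j: int
    z: float
    p_raw: float
    p_holm: float
    p_shaffer: float
    significant_holm: bool
    significant_shaffer: bool


@dataclass
class PosthocResult:
    pairs: list[PosthocPair]
    alpha: float
    mean_ranks: np.ndarray
    n_used: int
    n_dropped: int
    statistic_name: str = ""


def _clean(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop rows containing NaN (listwise); return data and drop count."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("expected an N x K table")
    keep = ~np.isnan(values).any(axis=1)
    return values[keep], int((~keep).sum())


def friedman(values: np.ndarray) -> FriedmanResult:
    """Friedman test over an N-image x K-level table.

    Uses within-row mid-ranks and the tie-corrected chi-square statistic

        chi2 = (K-1) (sum_j R_j^2 - N^2 K (K+1)^2 / 4)
               / (sum_ij r_ij^2 - N K (K+1)^2 / 4)

    with K - 1 degrees of freedom.  A table whose rows are all constant
    yields statistic 0 and p = 1.
    """
    data, dropped = _clean(values)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    ranks = sps.rankdata(data, axis=1)
    col_sums = ranks.sum(axis=0)
    correction = n * k * (k + 1) ** 2 / 4.0
    num = (k - 1) * (np.sum(col_sums**2) - n * correction)
    den = np.sum(ranks**2) - correction
    if den <= 0:
        return FriedmanResult(0.0, 1.0, n, dropped, k)
    stat = float(num / den)
    p = float(sps.chi2.sf(stat, k - 1))
    return FriedmanResult(stat, p, n, dropped, k)


@lru_cache(maxsize=None)
def shaffer_true_counts(k: int) -> tuple[int, ...]:
    """Possible counts of simultaneously true pairwise hypotheses.

    Among K levels, equality is transitive, so the true "level i equals
    level j" hypotheses are exactly the within-group pairs of some
    partition of the K levels: the achievable counts are
    { sum_g C(size_g, 2) } over all partitions.  Computed by the
    standard recursion over the size of the group containing one fixed
    element.
    """
    if k <= 1:
        return (0,)
    counts: set[int] = set()
    for j in range(1, k + 1):
        for rest in shaffer_true_counts(k - j):
            counts.add(comb(j, 2) + rest)
    return tuple(sorted(counts))


def shaffer_divisors(k: int) -> list[int]:
    """Static Shaffer divisor sequence for all K(K-1)/2 ordered pairs.

    At step i (p-values sorted ascending) the divisor is the largest
    achievable count of true hypotheses not exceeding m - i + 1.
    """
    m = comb(k, 2)
    counts = shaffer_true_counts(k)
    return [max(s for s in counts if s <= m - i) for i in range(m)]


def _step_down_adjust(p_raw: np.ndarray, divisors: np.ndarray) -> np.ndarray:
    """Step-down adjusted p-values: running max of divisor * p along the
    ascending-p order, clipped at 1, mapped back to input order."""
    order = np.argsort(p_raw, kind="stable")
    scaled = divisors * p_raw[order]
    adj_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty_like(adj_sorted)
    out[order] = adj_sorted
    return out


def pairwise_posthoc(
    values: np.ndarray,
    alpha: float = 0.05,
    levels: list[int] | None = None,
    statistic_name: str = "",
) -> PosthocResult:
    """All-pairs mean-rank comparison with Holm and Shaffer adjustment."""
    data, dropped = _clean(values)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if levels is None:
        levels = list(range(1, k + 1))
    ranks = sps.rankdata(data, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))

    idx_pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    z = np.array(
        [(mean_ranks[i] - mean_ranks[j]) / se for i, j in idx_pairs]
    )
    p_raw = 2.0 * sps.norm.sf(np.abs(z))

    m = len(idx_pairs)
    holm_div = np.arange(m, 0, -1, dtype=np.float64)
    shaf_div = np.array(shaffer_divisors(k), dtype=np.float64)
    p_holm = _step_down_adjust(p_raw, holm_div)
    p_shaffer = _step_down_adjust(p_raw, shaf_div)

    pairs = [
        PosthocPair(
            level_i=levels[i],
            level_j=levels[j],
            z=float(z[q]),
            p_raw=float(p_raw[q]),
            p_holm=float(p_holm[q]),
            p_shaffer=float(p_shaffer[q]),
            significant_holm=bool(p_holm[q] < alpha),
            significant_shaffer=bool(p_shaffer[q] < alpha),
        )
        for q, (i, j) in enumerate(idx_pairs)
    ]
    return PosthocResult(
        pairs=pairs,
        alpha=alpha,
        mean_ranks=mean_ranks,
        n_used=n,
        n_dropped=dropped,
        statistic_name=statistic_name,
    )


def nonsignificant_pairs(
    result: PosthocResult, alpha: float | None = None
) -> list[tuple[int, int]]:
    """Level pairs whose Shaffer-adjusted p is >= alpha."""
    if alpha is None:
        alpha = result.alpha
    return [
        (p.level_i, p.level_j)
        for p in result.pairs
        if p.p_shaffer >= alpha
    ]
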