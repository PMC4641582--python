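"""Independent brute-force oracles used by the test-suite.

Everything here is written without reference to the package internals:
per-pixel fuzzy C-means, flood-fill component bookkeeping for the
multi-level overlap rule, flat-loop feature statistics, permutation
Friedman nulls and set-partition enumeration for Shaffer's procedure.
"""

from __future__ import annotations

import math
from math import comb

import numpy as np
from scipy import stats as sps


def perpixel_fcm(image, c, m=2.0, max_iter=100, tol=1e-5):
    """Reference FCM on the raw pixel vector (no histogram weighting)."""
    x = np.asarray(image, dtype=float).ravel()
    v = np.linspace(x.min(), x.max(), c)
    trace = []
    for _ in range(max_iter):
        d2 = (x[:, None] - v[None, :]) ** 2
        zero = d2 <= 0
        anyz = zero.any(1)
        dmin = d2.min(1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = (dmin / d2) ** (1 / (m - 1))
        u = w / w.sum(1, keepdims=True)
        if anyz.any():
            z = zero[anyz].astype(float)
            u[anyz] = z / z.sum(1, keepdims=True)
        um = u**m
        den = um.sum(0)
        v = np.where(den > 0, um.T @ x / np.where(den > 0, den, 1), v)
        d2 = (x[:, None] - v[None, :]) ** 2
        obj = float((um * d2).sum())
        trace.append(obj)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < tol:
            break
    return np.sort(v), trace


def flood_components(mask):
    """8-connected components of a boolean mask as frozensets of (r, c)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            comp = []
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < h
                            and 0 <= cc < w
                            and mask[rr, cc]
                            and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(frozenset(comp))
    return comps


def replay_level_rule(segmented, thresholds):
    """Exhaustive pixel bookkeeping of the multi-level preservation rule.

    Returns, per level, the list of final region pixel sets: lower-level
    regions preserved whenever a looser-level component touches them,
    untouched components added as new regions.
    """
    segmented = np.asarray(segmented)
    accepted: list[frozenset] = []
    claimed: set = set()
    out = []
    for t in thresholds:
        mask = segmented <= t
        for comp in flood_components(mask):
            if comp & claimed:
                continue
            accepted.append(comp)
            claimed |= comp
        out.append(list(accepted))
    return out


def flat_loop_image_stats(regions):
    """Per-image statistics via plain python loops over region tuples.

    ``regions`` is a list of (area, (row, col), eccentricity).
    """
    n = len(regions)
    total = sum(a for a, _, _ in regions)
    if n == 0:
        return dict(n=0, total_area=0.0, mean_area=math.nan,
                    mean_nn=math.nan, mean_ecc=math.nan,
                    total_ecc=math.nan)
    mins = []
    for i, (_, ci, _) in enumerate(regions):
        best = math.inf
        for j, (_, cj, _) in enumerate(regions):
            if i == j:
                continue
            d = math.hypot(ci[0] - cj[0], ci[1] - cj[1])
            best = min(best, d)
        mins.append(best)
    mean_nn = sum(mins) / n if n >= 2 else math.nan
    total_ecc = sum(e for _, _, e in regions)
    return dict(
        n=n,
        total_area=float(total),
        mean_area=total / n,
        mean_nn=mean_nn,
        mean_ecc=total_ecc / n,
        total_ecc=total_ecc,
    )


def flat_loop_cohort_stats(image_stats):
    """Cohort statistics via plain loops over per-image stat dicts."""
    total_regions = sum(s["n"] for s in image_stats)
    total_area = sum(s["total_area"] for s in image_stats)
    nn = [s["mean_nn"] for s in image_stats
          if not math.isnan(s["mean_nn"])]
    ecc = [s["mean_ecc"] for s in image_stats
           if not math.isnan(s["mean_ecc"])]
    return dict(
        total_regions=total_regions,
        total_area=float(total_area),
        pooled_mean_area=(
            total_area / total_regions if total_regions else math.nan
        ),
        mean_nn=sum(nn) / len(nn) if nn else math.nan,
        mean_ecc=sum(ecc) / len(ecc) if ecc else math.nan,
    )


def set_partitions(items):
    """All partitions of a list into non-empty groups."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for p in set_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [p[i] + [first]] + p[i + 1 :]
        yield [[first]] + p


def shaffer_counts_by_enumeration(k):
    """Achievable counts of true pairwise equalities among k levels."""
    return tuple(
        sorted(
            {
                sum(comb(len(g), 2) for g in p)
                for p in set_partitions(list(range(k)))
            }
        )
    )


def permutation_friedman_pvalue(table, statistic, n_perm=20000, seed=0):
    """Monte-Carlo Friedman null: permute within rows, recompute the
    tie-corrected statistic, return the tail fraction >= observed."""
    rng = np.random.default_rng(seed)
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    count = 0
    for _ in range(n_perm):
        perm = np.take_along_axis(
            table, np.argsort(rng.uniform(size=table.shape), axis=1), axis=1
        )
        ranks = sps.rankdata(perm, axis=1)
        cs = ranks.sum(axis=0)
        corr = n * k * (k + 1) ** 2 / 4
        num = (k - 1) * ((cs**2).sum() - n * corr)
        den = (ranks**2).sum() - corr
        stat = num / den if den > 0 else 0.0
        if stat >= statistic - 1e-12:
            count += 1
    return count / n_perm
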