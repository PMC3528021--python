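"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive (per-base labeling, O(n^2) scans,
exhaustive enumeration) and shares no code with the implementation.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Tuple

import numpy as np


def label_bases(length: int, coding: Sequence[Tuple[int, int]],
                lincrna: Sequence[Tuple[int, int]]) -> np.ndarray:
    """Per-base compartment labels for one chromosome.

    0 = intergenic (non-lincRNA), 1 = genic, 2 = lincRNA.  Genic wins where
    a corrupt input overlaps; callers ensure disjointness when needed.
    """
    lab = np.zeros(length, dtype=np.int8)
    for s, e in lincrna:
        lab[s:e] = 2
    for s, e in coding:
        lab[s:e] = 1
    return lab


def dissect_by_bases(start: int, end: int, labels: np.ndarray) -> Tuple[int, int, int]:
    window = labels[start:end]
    return (
        int((window == 1).sum()),
        int((window == 2).sum()),
        int((window == 0).sum()),
    )


def pairwise_overlaps(intervals: Sequence[Tuple[str, int, int]]) -> List[Tuple[int, int]]:
    """All overlapping pairs by O(n^2) comparison."""
    hits = []
    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and min(ei, ej) > max(si, sj):
                hits.append((i, j))
    return hits


def probes_in_intervals(
    probes: Sequence[Tuple[str, int]], intervals: Sequence[Tuple[str, int, int, str]]
) -> List[Tuple[int, str]]:
    """Point-in-interval scan: (probe index, gene id) for every containment."""
    out = []
    for i, (pc, pp) in enumerate(probes):
        for ic, s, e, gid in intervals:
            if pc == ic and s <= pp < e:
                out.append((i, gid))
    return out


def overlap_bp_naive(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def best_single_split(values: np.ndarray, m: int) -> Tuple[int, float]:
    """Exhaustive two-sample t-statistic scan (leftmost maximizer)."""
    n = len(values)
    best_k, best_t = -1, -1.0
    for k in range(m, n - m + 1):
        left, right = values[:k], values[k:]
        v1 = ((left - left.mean()) ** 2).sum()
        v2 = ((right - right.mean()) ** 2).sum()
        pooled = (v1 + v2) / (n - 2)
        diff = abs(left.mean() - right.mean())
        if pooled <= 0:
            t = float("inf") if diff > 1e-12 else 0.0
        else:
            t = diff / np.sqrt(pooled * (1.0 / k + 1.0 / (n - k)))
        if t > best_t:
            best_k, best_t = k, t
    return best_k, best_t


def wilcoxon_enumerate(differences: Sequence[float]) -> Tuple[float, float]:
    """Exact two-tailed signed-rank test by enumerating 2^n sign vectors."""
    d = np.asarray([x for x in differences if x != 0], dtype=float)
    n = d.size
    absd = np.abs(d)
    # average ranks, computed from scratch
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    lower = float(np.mean(ws <= w_obs + 1e-12))
    upper = float(np.mean(ws >= w_obs - 1e-12))
    return float(w_obs), min(1.0, 2.0 * min(lower, upper))


def ols_normal_equations(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Closed-form simple OLS via the normal equations, plus R^2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxx = (x * x).sum() - x.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot
    return float(slope), float(intercept), float(r2)
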