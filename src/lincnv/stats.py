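"""Inferential layer: exact two-tailed Wilcoxon signed-rank test and
ordinary least-squares regression with R^2."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: sample size above which the normal approximation replaces enumeration
EXACT_N_MAX = 25


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float   # W = sum of ranks of positive differences
    pvalue: float      # two-tailed
    n: int             # sample size after dropping zero differences
    zeros_dropped: int
    exact: bool


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def _exact_null_pmf(ranks: np.ndarray) -> np.ndarray:
    """Null distribution of 2*W by polynomial convolution.

    Average ranks are multiples of 0.5, so doubling makes them integers and
    the distribution of 2*W is supported on 0..sum(2*ranks).  Each rank
    enters the positive-rank sum independently with probability 1/2; the
    pmf is the normalized product of (1 + x^{2r}) factors.  Exact for any
    tie pattern, equivalent to enumerating all 2^n sign assignments.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    pmf = np.zeros(int(r2.sum()) + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: pmf.size - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(differences) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (n reduced), ties receive average ranks.
    For n <= 25 the p-value is exact under the permutation null over all
    2^n sign assignments; larger n uses the normal approximation with
    continuity and tie corrections.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1:
        raise ValueError("differences must be one-dimensional")
    nonzero = d[d != 0]
    zeros = d.size - nonzero.size
    n = nonzero.size
    if n == 0:
        raise ValueError("all differences are zero: test undefined")
    ranks = sps.rankdata(np.abs(nonzero))
    w = float(ranks[nonzero > 0].sum())
    if n <= EXACT_N_MAX:
        pmf = _exact_null_pmf(ranks)
        w2 = int(round(2.0 * w))
        lower = pmf[: w2 + 1].sum()
        upper = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
        return WilcoxonResult(w, float(p), n, zeros, exact=True)
    # normal approximation with continuity correction; tie correction on the
    # variance follows the standard adjustment
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(nonzero), return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(w, float(min(1.0, p)), n, zeros, exact=False)


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with coefficient of determination."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = xv.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant: regression undefined")
    slope, intercept = np.polyfit(xv, yv, 1)
    resid = yv - (intercept + slope * xv)
    ss_res = float((resid**2).sum())
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2 = min(1.0, max(0.0, r2))  # guard numerical round-off at the edges
    return RegressionResult(float(slope), float(intercept), float(r2), n)


def fold_ratio(numerator, denominator) -> float:
    """Ratio of means (not mean of ratios) of two paired proportion vectors."""
    num = float(np.mean(np.asarray(numerator, dtype=float)))
    den = float(np.mean(np.asarray(denominator, dtype=float)))
    if den == 0:
        raise ValueError("denominator mean is zero: fold ratio undefined")
    return num / den
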