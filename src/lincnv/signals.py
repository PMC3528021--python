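"""Per-probe signal arithmetic and conditioning.

Probe tables are pandas DataFrames with columns ``name``, ``chrom``,
``pos`` (0-based), ``lrr``, ``baf``, ``genotype`` and optionally ``gc``.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .genome import Y_NAMES, chrom_sort_key

log = logging.getLogger(__name__)

GENOTYPES = ("AA", "AB", "BB", "NC")

#: sample quality threshold; scores above it trigger a warning (lower = better)
QUALITY_WARN_THRESHOLD = 0.02


def compute_lrr(r_subject, r_expected):
    """log2 ratio of observed to expected total intensity.

    Accepts scalars or arrays; non-positive intensities are an error.
    """
    rs = np.asarray(r_subject, dtype=float)
    re = np.asarray(r_expected, dtype=float)
    if np.any(rs <= 0) or np.any(re <= 0):
        raise ValueError("intensities must be strictly positive")
    out = np.log2(rs / re)
    return float(out) if out.ndim == 0 else out


def compute_baf(a, b):
    """B-allele fraction B/(A+B); total intensity of zero is uncallable."""
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if np.any(aa < 0) or np.any(bb < 0):
        raise ValueError("allele intensities must be non-negative")
    tot = aa + bb
    if np.any(tot == 0):
        raise ValueError("A + B must be positive (uncallable probe)")
    out = bb / tot
    return float(out) if out.ndim == 0 else out


def filter_probes(signals: pd.DataFrame, drop_no_calls: bool = True) -> pd.DataFrame:
    """Drop Y-chromosome probes and (optionally) no-call genotypes.

    Order is preserved; the operation is idempotent.  ``drop_no_calls``
    applies the NC filter — use it on the normal sample, whose genotypes
    define probe informativeness.
    """
    keep = ~signals["chrom"].isin(Y_NAMES)
    if drop_no_calls:
        keep &= signals["genotype"] != "NC"
    return signals.loc[keep].reset_index(drop=True)


def combine_replicates(replicates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average replicate arrays probe-wise.

    LRR and BAF become arithmetic means; the genotype is taken from the
    first replicate, demoted to NC where replicates disagree.  Replicates
    must share the probe set exactly.
    """
    if not replicates:
        raise ValueError("no replicates given")
    first = replicates[0].reset_index(drop=True)
    if len(replicates) == 1:
        return first.copy()
    ref_names = first["name"]
    aligned: List[pd.DataFrame] = [first]
    for rep in replicates[1:]:
        if set(rep["name"]) != set(ref_names):
            raise ValueError("replicates do not share the same probe set")
        aligned.append(rep.set_index("name").loc[ref_names].reset_index())
    out = first.copy()
    out["lrr"] = np.mean([r["lrr"].to_numpy() for r in aligned], axis=0)
    out["baf"] = np.mean([r["baf"].to_numpy() for r in aligned], axis=0)
    gt = first["genotype"].to_numpy().copy()
    for rep in aligned[1:]:
        gt = np.where(rep["genotype"].to_numpy() == gt, gt, "NC")
    out["genotype"] = gt
    return out


def gc_correct(signals: pd.DataFrame, robust: bool = False) -> pd.DataFrame:
    """Remove a linear GC-wave trend from LRR.

    Fits a line of LRR on the stored per-probe GC covariate and replaces
    LRR with residual + grand mean, so the mean LRR is preserved.  BAF is
    untouched.  A constant GC covariate makes the fit degenerate: the
    correction is skipped with a warning.

    ``robust=False`` uses ordinary least squares.  On aberration-rich
    genomes OLS leaks copy-number signal into the slope (events that
    happen to correlate with GC bias the wave estimate), so the pipeline
    passes ``robust=True``, which estimates the slope by Theil-Sen on a
    deterministic subsample of probes.
    """
    if "gc" not in signals.columns:
        raise ValueError("signals lack a 'gc' covariate column")
    if len(signals) < 3:
        raise ValueError("need at least 3 probes for GC correction")
    gc = signals["gc"].to_numpy(dtype=float)
    lrr = signals["lrr"].to_numpy(dtype=float)
    if np.ptp(gc) == 0:
        warnings.warn("GC covariate is constant; correction skipped", stacklevel=2)
        return signals.copy()
    if robust:
        from scipy.stats import theilslopes

        step = max(1, len(lrr) // 1500)  # Theil-Sen is O(n^2); subsample
        slope = theilslopes(lrr[::step], gc[::step]).slope
    else:
        slope, _ = np.polyfit(gc, lrr, 1)
    out = signals.copy()
    out["lrr"] = lrr - slope * (gc - gc.mean())
    return out


def pair_adjust(tumor: pd.DataFrame, normal: pd.DataFrame) -> pd.DataFrame:
    """Matched-pair adjustment: tumor LRR minus normal LRR per probe.

    Both inputs must carry the same probe set; the result is sorted by
    (chromosome, position) and carries the tumor BAF plus the normal
    genotype, which downstream LOH detection conditions on.
    """
    if set(tumor["name"]) != set(normal["name"]):
        raise ValueError("tumor and normal probe sets differ; filter/intersect first")
    t = tumor.set_index("name")
    n = normal.set_index("name")
    n = n.loc[t.index]
    if not (t["pos"].to_numpy() == n["pos"].to_numpy()).all():
        raise ValueError("probe positions disagree between tumor and normal")
    paired = pd.DataFrame(
        {
            "name": t.index,
            "chrom": t["chrom"].to_numpy(),
            "pos": t["pos"].to_numpy(),
            "lrr": t["lrr"].to_numpy() - n["lrr"].to_numpy(),
            "baf": t["baf"].to_numpy(),
            "genotype": n["genotype"].to_numpy(),
        }
    )
    if "gc" in tumor.columns:
        paired["gc"] = t["gc"].to_numpy()
    key = paired["chrom"].map(chrom_sort_key)
    paired = paired.iloc[np.lexsort((paired["pos"].to_numpy(), key.to_numpy()))]
    return paired.reset_index(drop=True)


def quality_score(signals: pd.DataFrame, warn_threshold: float = QUALITY_WARN_THRESHOLD) -> float:
    """Robust per-probe LRR noise estimate; lower is better.

    Median absolute difference of consecutive-probe LRRs within each
    chromosome, divided by sqrt(2).  For i.i.d. Gaussian noise of sd sigma
    this converges to ~0.674*sigma.
    """
    if len(signals) < 2:
        raise ValueError("need at least 2 probes for a quality score")
    diffs: List[np.ndarray] = []
    for _, group in signals.groupby("chrom", sort=False):
        lrr = group.sort_values("pos")["lrr"].to_numpy(dtype=float)
        if len(lrr) >= 2:
            diffs.append(np.abs(np.diff(lrr)))
    if not diffs:
        raise ValueError("no chromosome has 2+ probes")
    score = float(np.median(np.concatenate(diffs)) / math.sqrt(2.0))
    if score > warn_threshold:
        log.warning("quality score %.4f exceeds %.2f (lower is better)",
                    score, warn_threshold)
    return score
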