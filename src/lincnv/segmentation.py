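"""Change-point segmentation of paired LRR / mirrored-BAF signals and
classification of segments into CNV event classes.

Recursive binary segmentation with a two-sample t-statistic stopping rule
stands in for the proprietary segmentation stage: at each step the split
maximizing |t| between the left and right means is accepted iff |t| >= T
and both sides keep >= m probes, then both sides are segmented recursively.
Breakpoints from the paired-LRR scan and from the mirrored-BAF scan (over
probes heterozygous in the normal) are unioned before classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

EVENT_CLASSES = ("gain", "loss", "homozygous_loss", "allelic_imbalance", "neutral")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the calling stage; every default is configuration, not
    a claim about the source platform."""

    t_threshold: float = 5.0        # stopping threshold T on |t|
    min_seg_probes: int = 5         # m: min probes on each side of a split
    gain_lrr: float = 0.25          # mean paired LRR >= -> gain
    loss_lrr: float = -0.25         # mean paired LRR <= -> loss
    homozygous_lrr: float = -1.1    # mean paired LRR <= -> homozygous loss
    dev_threshold: float = 0.15     # mirrored-BAF deviation >= -> allelic imbalance
    min_call_probes: int = 5        # non-neutral calls below this are demoted

    def __post_init__(self) -> None:
        if self.t_threshold < 0:
            raise ValueError("t_threshold must be >= 0")
        if self.min_seg_probes < 2:
            raise ValueError("min_seg_probes must be >= 2")
        if self.min_call_probes < 2:
            raise ValueError("min_call_probes must be >= 2")
        if not (self.homozygous_lrr <= self.loss_lrr < 0 < self.gain_lrr):
            raise ValueError("LRR thresholds must satisfy homozygous <= loss < 0 < gain")


@dataclass
class Segment:
    """A contiguous run of probes with summary statistics.

    ``start``/``end`` are 0-based half-open bp derived from the first and
    last supporting probe (end = last probe position + 1).
    """

    chrom: str
    start: int
    end: int
    n_probes: int
    mean_lrr: float
    mean_dev: float  # NaN when no informative (AB-in-normal) probe
    probe_names: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must precede end")
        if self.n_probes < 1:
            raise ValueError("segment needs >= 1 probe")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CNVCall(Segment):
    """A classified segment.  ``loh`` flags loss calls whose BAF deviation
    also satisfies the allelic-imbalance criterion (LOH co-annotation)."""

    event_class: str = "neutral"
    sample: str = ""
    loh: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")


def mirrored_baf_deviation(bafs: Sequence[float]) -> float:
    """Mean |BAF - 0.5| over probes heterozygous in the matched normal.

    0 for balanced heterozygosity, 0.5 for complete loss of heterozygosity.
    Raises when no informative probe is supplied; callers then classify on
    LRR alone.
    """
    arr = np.asarray(bafs, dtype=float)
    if arr.size == 0:
        raise ValueError("no informative probes: deviation undefined")
    return float(np.abs(arr - 0.5).mean())


def _best_split(values: np.ndarray, lo: int, hi: int, m: int,
                csum: np.ndarray, csum2: np.ndarray) -> Tuple[int, float]:
    """Leftmost split index k in [lo+m, hi-m] maximizing the pooled
    two-sample |t| between values[lo:k] and values[k:hi]."""
    n = hi - lo
    ks = np.arange(lo + m, hi - m + 1)
    if ks.size == 0:
        return -1, 0.0
    n1 = ks - lo
    n2 = hi - ks
    s1 = csum[ks] - csum[lo]
    s2 = csum[hi] - csum[ks]
    q1 = csum2[ks] - csum2[lo]
    q2 = csum2[hi] - csum2[ks]
    m1 = s1 / n1
    m2 = s2 / n2
    ss = np.maximum(q1 - n1 * m1 * m1, 0.0) + np.maximum(q2 - n2 * m2 * m2, 0.0)
    pooled = ss / (n - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    diff = np.abs(m1 - m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff > 1e-12, np.inf, 0.0))
    k = int(np.argmax(t))  # argmax takes the first (leftmost) maximizer
    return int(ks[k]), float(t[k])


def segment_signal(values: Sequence[float], t_threshold: float, min_probes: int) -> List[int]:
    """Recursive binary segmentation; returns sorted interior breakpoints.

    A breakpoint at index k separates values[:k] from values[k:].  The
    leftmost maximizer is chosen on ties so results are deterministic.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    m = int(min_probes)
    if m < 2:
        raise ValueError("min_probes must be >= 2")
    if n < 2 * m:
        return []
    csum = np.concatenate([[0.0], np.cumsum(v)])
    csum2 = np.concatenate([[0.0], np.cumsum(v * v)])
    breakpoints: List[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * m:
            continue
        k, t = _best_split(v, lo, hi, m, csum, csum2)
        if k < 0 or t < t_threshold:
            continue
        breakpoints.append(k)
        stack.append((lo, k))
        stack.append((k, hi))
    return sorted(breakpoints)


def classify_segment(mean_lrr: float, mean_dev: float, params: SegmentationParams) -> str:
    """Event class from mean paired LRR and mirrored-BAF deviation.

    Precedence: homozygous_loss > loss/gain > allelic_imbalance > neutral.
    A NaN deviation (no informative probes) disables the imbalance rule.
    """
    if mean_lrr <= params.homozygous_lrr:
        return "homozygous_loss"
    if mean_lrr >= params.gain_lrr:
        return "gain"
    if mean_lrr <= params.loss_lrr:
        return "loss"
    if not math.isnan(mean_dev) and mean_dev >= params.dev_threshold:
        return "allelic_imbalance"
    return "neutral"


def _segment_stats(chrom: str, pos: np.ndarray, lrr: np.ndarray, dev: np.ndarray,
                   het: np.ndarray, names: np.ndarray, lo: int, hi: int,
                   params: SegmentationParams, sample: str) -> CNVCall:
    seg_dev = dev[lo:hi][het[lo:hi]]
    mean_dev = float(seg_dev.mean()) if seg_dev.size else float("nan")
    mean_lrr = float(lrr[lo:hi].mean())
    cls = classify_segment(mean_lrr, mean_dev, params)
    loh = (
        cls in ("loss", "homozygous_loss")
        and not math.isnan(mean_dev)
        and mean_dev >= params.dev_threshold
    )
    return CNVCall(
        chrom=chrom,
        start=int(pos[lo]),
        end=int(pos[hi - 1]) + 1,
        n_probes=hi - lo,
        mean_lrr=mean_lrr,
        mean_dev=mean_dev,
        probe_names=tuple(names[lo:hi]),
        event_class=cls,
        sample=sample,
        loh=loh,
    )


def call_cnvs(paired: pd.DataFrame, params: SegmentationParams | None = None,
              sample: str = "") -> List[CNVCall]:
    """Segment and classify a paired-signal table into CNV calls.

    Per chromosome, breakpoints from the paired-LRR scan and the
    mirrored-BAF scan (AB-in-normal probes only) are unioned; the resulting
    segments are classified, adjacent same-class segments merged, and
    non-neutral calls with fewer than ``min_call_probes`` probes demoted to
    neutral.  The returned calls tile each chromosome (neutral included).
    """
    params = params or SegmentationParams()
    if len(paired) == 0:
        return []
    calls: List[CNVCall] = []
    for chrom, group in paired.groupby("chrom", sort=False):
        group = group.sort_values("pos")
        pos = group["pos"].to_numpy(dtype=np.int64)
        lrr = group["lrr"].to_numpy(dtype=float)
        baf = group["baf"].to_numpy(dtype=float)
        het = (group["genotype"].to_numpy() == "AB")
        names = group["name"].to_numpy()
        dev = np.abs(baf - 0.5)
        n = len(pos)

        cut_positions: set = set()
        for k in segment_signal(lrr, params.t_threshold, params.min_seg_probes):
            cut_positions.add(int(pos[k]))
        het_idx = np.flatnonzero(het)
        if het_idx.size >= 2 * params.min_seg_probes:
            for j in segment_signal(dev[het_idx], params.t_threshold, params.min_seg_probes):
                cut_positions.add(int(pos[het_idx[j]]))
        # map cut positions back to full-probe indices
        cuts = sorted(int(np.searchsorted(pos, p, side="left")) for p in cut_positions)
        bounds = [0] + [c for c in cuts if 0 < c < n] + [n]

        segs = [
            _segment_stats(chrom, pos, lrr, dev, het, names, lo, hi, params, sample)
            for lo, hi in zip(bounds[:-1], bounds[1:])
        ]
        segs = _merge_adjacent(segs, chrom, pos, lrr, dev, het, names, params, sample)
        # demote short non-neutral calls, then re-merge neutrals
        demote = [
            s.event_class != "neutral" and s.n_probes < params.min_call_probes
            for s in segs
        ]
        if any(demote):
            for s, d in zip(segs, demote):
                if d:
                    s.event_class = "neutral"
                    s.loh = False
            segs = _merge_adjacent(segs, chrom, pos, lrr, dev, het, names, params, sample)
        calls.extend(segs)
    return calls


def _merge_adjacent(segs: List[CNVCall], chrom: str, pos: np.ndarray, lrr: np.ndarray,
                    dev: np.ndarray, het: np.ndarray, names: np.ndarray,
                    params: SegmentationParams, sample: str) -> List[CNVCall]:
    """Merge runs of adjacent same-class segments, recomputing statistics
    over the merged probe range (classes are kept from the inputs)."""
    if not segs:
        return segs
    merged: List[CNVCall] = []
    lo = 0
    offsets = np.concatenate([[0], np.cumsum([s.n_probes for s in segs])])
    i = 0
    while i < len(segs):
        j = i
        while j + 1 < len(segs) and segs[j + 1].event_class == segs[i].event_class:
            j += 1
        lo, hi = int(offsets[i]), int(offsets[j + 1])
        seg = _segment_stats(chrom, pos, lrr, dev, het, names, lo, hi, params, sample)
        seg.event_class = segs[i].event_class
        seg.loh = (
            seg.event_class in ("loss", "homozygous_loss")
            and not math.isnan(seg.mean_dev)
            and seg.mean_dev >= params.dev_threshold
        )
        merged.append(seg)
        i = j + 1
    return merged


def calls_to_frame(calls: Sequence[CNVCall]) -> pd.DataFrame:
    """Tabular view of calls (coordinates stay 0-based half-open)."""
    return pd.DataFrame(
        [
            {
                "sample": c.sample,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "n_probes": c.n_probes,
                "mean_lrr": c.mean_lrr,
                "mean_dev": c.mean_dev,
                "event_class": c.event_class,
                "loh": c.loh,
                "length": c.length,
            }
            for c in calls
        ],
        columns=[
            "sample", "chrom", "start", "end", "n_probes", "mean_lrr",
            "mean_dev", "event_class", "loh", "length",
        ],
    )
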