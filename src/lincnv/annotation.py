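"""Genomic interval tracks, lincRNA reference construction and compartment
dissection of copy-number calls.

All coordinates are 0-based half-open.  A "compartment" is one of three
disjoint labels on the genome: genic (merged protein-coding footprint),
lincRNA (intergenic lincRNA footprint) and the remaining non-lincRNA
intergenic space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeModel, Y_NAMES, chrom_sort_key

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Interval:
    """One gene-level interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    gene_id: str
    biotype: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} ({self.gene_id})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class AnnotationTrack:
    """A named collection of intervals with unique gene identifiers."""

    def __init__(self, name: str, intervals: Iterable[Interval]):
        self.name = name
        ivs = sorted(intervals, key=lambda iv: (chrom_sort_key(iv.chrom), iv.start, iv.end))
        ids = [iv.gene_id for iv in ivs]
        if len(ids) != len(set(ids)):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers in track {name!r}: {dup[:5]}")
        self.intervals: List[Interval] = ivs
        self._by_chrom: Dict[str, List[Interval]] = {}
        for iv in ivs:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        self._merged_cache: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AnnotationTrack)
            and self.name == other.name
            and self.intervals == other.intervals
        )

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(self._by_chrom)

    def on(self, chrom: str) -> List[Interval]:
        return self._by_chrom.get(chrom, [])

    def merged(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """Merged (starts, ends) arrays covering this track on ``chrom``."""
        if chrom not in self._merged_cache:
            ivs = self.on(chrom)
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            self._merged_cache[chrom] = merge_intervals(starts, ends)
        return self._merged_cache[chrom]

    def merged_bp(self, chroms: Sequence[str] | None = None) -> int:
        """Total merged coverage in bp, optionally restricted to ``chroms``."""
        names = self.chroms if chroms is None else [c for c in chroms if c in self._by_chrom]
        total = 0
        for chrom in names:
            starts, ends = self.merged(chrom)
            total += int((ends - starts).sum())
        return total


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping sorted-by-start intervals into disjoint runs.

    Abutting intervals (end == next start) are merged; half-open semantics
    make the result identical either way for coverage arithmetic.
    """
    if len(starts) == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s, out_e = [int(s[0])], [int(e[0])]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(e[i]))
        else:
            out_s.append(int(s[i]))
            out_e.append(int(e[i]))
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def overlap_bp(start: int, end: int, mstarts: np.ndarray, mends: np.ndarray) -> int:
    """Base pairs of [start, end) covered by disjoint merged intervals."""
    if len(mstarts) == 0 or start >= end:
        return 0
    ov = np.minimum(mends, end) - np.maximum(mstarts, start)
    return int(ov[ov > 0].sum())


def build_intergenic_lincrna_reference(
    candidates: AnnotationTrack, coding: AnnotationTrack
) -> Tuple[AnnotationTrack, List[str]]:
    """Retain candidate lincRNAs with zero bp of protein-coding overlap.

    Returns the intergenic-only reference track plus the identifiers that
    were dropped.  Candidates that merely abut a coding gene (shared
    boundary, 0 bp overlap under half-open coordinates) are retained.
    """
    kept, dropped = [], []
    for iv in candidates:
        mstarts, mends = coding.merged(iv.chrom)
        if overlap_bp(iv.start, iv.end, mstarts, mends) > 0:
            dropped.append(iv.gene_id)
        else:
            kept.append(iv)
    if dropped:
        log.info(
            "dropped %d/%d candidate lincRNAs overlapping coding genes: %s",
            len(dropped), len(candidates), ", ".join(dropped[:10]),
        )
    return AnnotationTrack("lincRNA_intergenic", kept), dropped


def map_probes_to_track(
    probes: pd.DataFrame, track: AnnotationTrack
) -> Tuple[pd.DataFrame, pd.Series]:
    """Assign probes to track intervals containing them.

    ``probes`` needs columns ``name``, ``chrom``, ``pos`` and must be sorted
    by (chrom, pos).  A probe inside two overlapping intervals yields one
    assignment row per interval.  Returns (assignments, per-gene counts);
    assignments has columns name/chrom/pos/gene_id.
    """
    rows: List[Tuple[str, str, int, str]] = []
    for chrom, group in probes.groupby("chrom", sort=False):
        ivs = track.on(chrom)
        if not ivs:
            continue
        pos = group["pos"].to_numpy()
        names = group["name"].to_numpy()
        for iv in ivs:
            lo = np.searchsorted(pos, iv.start, side="left")
            hi = np.searchsorted(pos, iv.end, side="left")
            for k in range(lo, hi):
                rows.append((names[k], chrom, int(pos[k]), iv.gene_id))
    assign = pd.DataFrame(rows, columns=["name", "chrom", "pos", "gene_id"])
    counts = assign.groupby("gene_id")["name"].count() if len(assign) else pd.Series(dtype=int)
    counts.name = "n_probes"
    return assign, counts


def intersect_calls_with_track(calls: Sequence, track: AnnotationTrack) -> pd.DataFrame:
    """Associate CNV calls with track genes they overlap.

    ``calls`` are objects with chrom/start/end/event_class (and optionally
    sample) attributes; neutral calls are ignored.  One row per
    (gene, overlapping call) with overlap bp and percent of gene length.
    """
    rows = []
    for call in calls:
        if getattr(call, "event_class", None) == "neutral":
            continue
        for iv in track.on(call.chrom):
            ov = min(call.end, iv.end) - max(call.start, iv.start)
            if ov <= 0:
                continue
            rows.append(
                {
                    "gene_id": iv.gene_id,
                    "sample": getattr(call, "sample", ""),
                    "chrom": call.chrom,
                    "call_start": call.start,
                    "call_end": call.end,
                    "event_class": call.event_class,
                    "gene_start": iv.start,
                    "gene_end": iv.end,
                    "overlap_bp": int(ov),
                    "overlap_pct": 100.0 * ov / iv.length,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "sample", "chrom", "call_start", "call_end", "event_class",
            "gene_start", "gene_end", "overlap_bp", "overlap_pct",
        ],
    )


def _assert_disjoint_in_window(
    start: int, end: int, coding: AnnotationTrack, lincrna: AnnotationTrack, chrom: str
) -> None:
    cs, ce = coding.merged(chrom)
    ls, le = lincrna.merged(chrom)
    g = overlap_bp(start, end, cs, ce)
    l = overlap_bp(start, end, ls, le)
    if g + l > end - start:
        raise ValueError(
            f"lincRNA track overlaps coding track inside {chrom}:{start}-{end}; "
            "rebuild the intergenic reference"
        )
    # cross-check: union coverage must equal the sum when tracks are disjoint
    all_s = np.concatenate([cs, ls])
    all_e = np.concatenate([ce, le])
    us, ue = merge_intervals(all_s, all_e)
    if overlap_bp(start, end, us, ue) != g + l:
        raise ValueError(
            f"lincRNA/coding overlap detected inside {chrom}:{start}-{end}"
        )


def dissect_segment(
    call, coding: AnnotationTrack, lincrna: AnnotationTrack
) -> Tuple[int, int, int]:
    """Partition a call's bp into (genic, lincRNA, non-lincRNA intergenic).

    Overlapping coding genes are merged first so no base is double counted;
    the three tallies sum exactly to the call length.  A lincRNA interval
    overlapping a coding interval is corrupt input and raises.
    """
    chrom, start, end = call.chrom, call.start, call.end
    _assert_disjoint_in_window(start, end, coding, lincrna, chrom)
    cs, ce = coding.merged(chrom)
    ls, le = lincrna.merged(chrom)
    genic = overlap_bp(start, end, cs, ce)
    linc = overlap_bp(start, end, ls, le)
    other = (end - start) - genic - linc
    return genic, linc, other


@dataclass
class CompartmentSummary:
    """Per-sample compartment tallies of aberrant base pairs."""

    sample: str
    genic_bp: int
    lincrna_bp: int
    intergenic_bp: int  # non-lincRNA intergenic
    #: share of total CNV length per compartment, percent (sums to 100)
    share_pct: Dict[str, float]
    #: percent of each compartment's genome-wide footprint that is aberrant
    affected_pct: Dict[str, float]

    @property
    def total_bp(self) -> int:
        return self.genic_bp + self.lincrna_bp + self.intergenic_bp


def genome_compartment_sizes(
    coding: AnnotationTrack, lincrna: AnnotationTrack, genome: GenomeModel
) -> Dict[str, int]:
    """Genome-wide bp per compartment on analysis chromosomes (Y excluded)."""
    chroms = genome.analysis_names()
    genic = coding.merged_bp(chroms)
    linc = lincrna.merged_bp(chroms)
    total = genome.total_bp(exclude_y=True)
    return {"genic": genic, "lincrna": linc, "intergenic": total - genic - linc}


def compartment_percentages(
    calls_by_sample: Mapping[str, Sequence],
    coding: AnnotationTrack,
    lincrna: AnnotationTrack,
    genome: GenomeModel,
) -> Tuple[List[CompartmentSummary], Dict[str, float]]:
    """Compartment dissection aggregated per sample plus cohort means.

    Samples with zero aberrant bp get no share percentages and are excluded
    from cohort means.  The cohort dict reports mean shares, mean affected
    fractions and the genic/lincRNA fold ratio of mean shares.
    """
    sizes = genome_compartment_sizes(coding, lincrna, genome)
    summaries: List[CompartmentSummary] = []
    for sample, calls in calls_by_sample.items():
        g = l = o = 0
        for call in calls:
            if getattr(call, "event_class", "neutral") == "neutral":
                continue
            if call.chrom in Y_NAMES:
                continue
            dg, dl, do = dissect_segment(call, coding, lincrna)
            g, l, o = g + dg, l + dl, o + do
        total = g + l + o
        if total > 0:
            share = {
                "genic": 100.0 * g / total,
                "lincrna": 100.0 * l / total,
                "intergenic": 100.0 * o / total,
            }
        else:
            share = {}
        affected = {
            "genic": 100.0 * g / sizes["genic"] if sizes["genic"] else float("nan"),
            "lincrna": 100.0 * l / sizes["lincrna"] if sizes["lincrna"] else float("nan"),
            "intergenic": 100.0 * o / sizes["intergenic"] if sizes["intergenic"] else float("nan"),
        }
        summaries.append(CompartmentSummary(sample, g, l, o, share, affected))

    with_cnv = [s for s in summaries if s.total_bp > 0]
    cohort: Dict[str, float] = {"n_samples": float(len(summaries)), "n_with_cnv": float(len(with_cnv))}
    if with_cnv:
        for comp in ("genic", "lincrna", "intergenic"):
            cohort[f"mean_share_{comp}"] = float(np.mean([s.share_pct[comp] for s in with_cnv]))
            cohort[f"mean_affected_{comp}"] = float(np.mean([s.affected_pct[comp] for s in with_cnv]))
        if cohort["mean_share_lincrna"] > 0:
            cohort["genic_vs_lincrna_fold"] = (
                cohort["mean_share_genic"] / cohort["mean_share_lincrna"]
            )
    return summaries, cohort


def aggregate_frequencies(
    calls_by_sample: Mapping[str, Sequence],
    genome: GenomeModel,
    bin_size: int,
) -> pd.DataFrame:
    """Per-bin cross-sample gain and loss frequencies.

    The genome (Y excluded) is tiled with fixed bins; a sample contributes
    to a bin's gain (loss) frequency when >= 1 bp of a gain (loss or
    homozygous_loss) call overlaps the bin.  Frequencies are counts / n.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    samples = list(calls_by_sample)
    n = len(samples)
    if n == 0:
        raise ValueError("need at least one sample")
    frames = []
    for chrom in genome.analysis_names():
        length = genome.length(chrom)
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        gains = np.zeros((len(starts), n), dtype=bool)
        losses = np.zeros((len(starts), n), dtype=bool)
        for j, sample in enumerate(samples):
            for call in calls_by_sample[sample]:
                if call.chrom != chrom:
                    continue
                cls = getattr(call, "event_class", "neutral")
                if cls == "gain":
                    target = gains
                elif cls in ("loss", "homozygous_loss"):
                    target = losses
                else:
                    continue
                lo = call.start // bin_size
                hi = (call.end - 1) // bin_size
                target[lo : hi + 1, j] = True
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "gain_freq": gains.sum(axis=1) / n,
                    "loss_freq": losses.sum(axis=1) / n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
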