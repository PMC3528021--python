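"""Synthetic cohort generator: toy genomes with annotation tracks, planted
CNV/LOH events, paired tumor-normal probe signals and qPCR Ct tables.

The signal model: for tumor purity rho and a planted event with total copy
number CN_t carrying b copies of the B allele on probes heterozygous in
the normal,

    expected LRR = log2(((1 - rho) * 2 + rho * CN_t) / 2)
    expected BAF = ((1 - rho) * g + rho * b_probe) / ((1 - rho) * 2 + rho * CN_t)

where g is the normal genotype's B-allele count and b_probe is b for
g == 1, 0 for g == 0 and CN_t for g == 2.  Gaussian noise, a smooth
GC-correlated wave and clipping of BAF to [0, 1] complete the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import AnnotationTrack, Interval
from .genome import GenomeModel

EVENT_CLASS_WEIGHTS = {
    "gain": 0.25,
    "loss": 0.40,
    "homozygous_loss": 0.15,
    "allelic_imbalance": 0.20,
}

DEFAULT_CHROM_LENGTHS = {"chr1": 20_000_000, "chr2": 15_000_000, "chr3": 10_000_000}


def classify_copy_state(cn_total: int, cn_b: int) -> Optional[str]:
    """Event class implied by a copy state; None for the normal diploid
    heterozygous-capable state (CN_t = 2, b = 1)."""
    if cn_total > 2:
        return "gain"
    if cn_total == 1:
        return "loss"
    if cn_total == 0:
        return "homozygous_loss"
    if cn_total == 2 and cn_b in (0, 2):
        return "allelic_imbalance"
    return None


@dataclass(frozen=True)
class EventSpec:
    """One requested aberration for one sample (0-based half-open)."""

    sample: str
    chrom: str
    start: int
    end: int
    cn_total: int
    cn_b: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid event interval {self.start}-{self.end}")
        if not (0 <= self.cn_b <= self.cn_total or self.cn_total == 0 and self.cn_b == 0):
            raise ValueError("need 0 <= cn_b <= cn_total")


@dataclass(frozen=True)
class PlantedEvent:
    """A planted aberration with its derived class and lincRNA overlaps."""

    chrom: str
    start: int
    end: int
    cn_total: int
    cn_b: int
    event_class: str
    lincrna_genes: Tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TruthSet:
    """Ground truth of a simulated cohort."""

    events: Dict[str, Tuple[PlantedEvent, ...]]  # sample -> events
    purity: Dict[str, float]

    @property
    def samples(self) -> Tuple[str, ...]:
        return tuple(self.events)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; defaults are desk-scale stand-ins,
    not claims about the source platform."""

    seed: int = 0
    n_pairs: int = 7
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    spacing: float = 700.0            # mean inter-probe gap, bp
    purity: float | Sequence[float] = 1.0
    lrr_noise_sd: float = 0.15
    baf_noise_sd: float = 0.03
    gc_wave_amplitude: float = 0.1    # LRR units over the GC range
    gc_wave_period: float = 5e6       # bp
    het_rate: float = 0.3
    nc_rate: float = 0.002            # no-call genotype rate in the normal
    replicates: int = 2
    lrr_floor: float = -4.0           # floor on expected LRR (homozygous loss)
    # annotation layout
    n_coding_genes: int = 60
    n_lincrnas: int = 25
    n_decoy_lincrnas: int = 3         # candidates overlapping coding genes
    coding_length_range: Tuple[int, int] = (20_000, 200_000)
    lincrna_length_range: Tuple[int, int] = (5_000, 50_000)
    # planted events: explicit specs win; otherwise auto-planting
    events: Optional[Tuple[EventSpec, ...]] = None
    events_per_sample: Tuple[int, int] = (2, 5)
    event_length_range: Tuple[int, int] = (100_000, 3_000_000)
    # qPCR
    qpcr_efficiency: float = 0.95
    qpcr_ct_noise_sd: float = 0.1
    qpcr_intercept: float = 30.0      # Ct at quantity 1
    qpcr_standard_quantities: Tuple[float, ...] = (64.0, 16.0, 4.0, 1.0, 0.25, 0.0625)
    qpcr_standard_replicates: int = 3
    qpcr_input_levels: Tuple[float, float] = (40.0, 10.0)
    qpcr_input_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.spacing <= 0:
            raise ValueError("probe spacing must be positive")
        for name in ("lrr_noise_sd", "baf_noise_sd", "qpcr_ct_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for rho in self.purities():
            if not (0.0 < rho <= 1.0):
                raise ValueError("tumor purity must lie in (0, 1]")
        if not (0.0 <= self.het_rate <= 1.0) or not (0.0 <= self.nc_rate < 1.0):
            raise ValueError("het_rate/nc_rate out of range")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0.0 < self.qpcr_efficiency <= 1.0):
            raise ValueError("amplification efficiency must lie in (0, 1]")
        if self.events is not None:
            for ev in self.events:
                if ev.chrom not in self.chrom_lengths:
                    raise ValueError(f"event chromosome {ev.chrom!r} not in genome")
                if ev.end > self.chrom_lengths[ev.chrom]:
                    raise ValueError(f"event {ev} exceeds chromosome bounds")

    def purities(self) -> List[float]:
        if isinstance(self.purity, (int, float)):
            return [float(self.purity)] * self.n_pairs
        vals = [float(v) for v in self.purity]
        if len(vals) != self.n_pairs:
            raise ValueError("purity list length must equal n_pairs")
        return vals

    def sample_ids(self) -> List[str]:
        return [f"S{i + 1}" for i in range(self.n_pairs)]


def _rng(config: SimulationConfig, stage: int, extra: int = 0) -> np.random.Generator:
    """Independent deterministic stream per (seed, stage, extra)."""
    return np.random.default_rng([int(config.seed), stage, extra])


def _place_disjoint(
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    n: int,
    length_range: Tuple[int, int],
    occupied: Dict[str, List[Tuple[int, int]]],
    max_tries: int = 2000,
) -> List[Tuple[str, int, int]]:
    """Place n intervals avoiding everything already in ``occupied``
    (updated in place).  Raises when the genome cannot fit them."""
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: List[Tuple[str, int, int]] = []
    for _ in range(n):
        for attempt in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            limit = chrom_lengths[chrom] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + length
            if all(end <= s or start >= e for s, e in occupied.get(chrom, [])):
                occupied.setdefault(chrom, []).append((start, end))
                placed.append((chrom, start, end))
                break
        else:
            raise ValueError(
                f"could not place {n} intervals of {length_range} bp in the genome"
            )
    return placed


def simulate_genome(
    config: SimulationConfig,
) -> Tuple[GenomeModel, AnnotationTrack, AnnotationTrack]:
    """Build the toy genome plus coding and candidate-lincRNA tracks.

    True lincRNAs are placed strictly in intergenic space; the candidate
    track additionally carries ``n_decoy_lincrnas`` intervals that overlap
    coding genes, exercising the intergenic-reference filter downstream.
    """
    genome = GenomeModel(dict(config.chrom_lengths), female=True)
    rng = _rng(config, stage=1)
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    coding_pos = _place_disjoint(
        rng, genome.chromosomes, config.n_coding_genes, config.coding_length_range, occupied
    )
    linc_pos = _place_disjoint(
        rng, genome.chromosomes, config.n_lincrnas, config.lincrna_length_range, occupied
    )
    coding = AnnotationTrack(
        "coding",
        [
            Interval(c, s, e, f"GENE{i + 1:04d}", "protein_coding")
            for i, (c, s, e) in enumerate(coding_pos)
        ],
    )
    candidates = [
        Interval(c, s, e, f"LINC{i + 1:04d}", "lincRNA")
        for i, (c, s, e) in enumerate(linc_pos)
    ]
    # decoys straddle a coding gene boundary so the reference builder drops them
    n_decoys = config.n_decoy_lincrnas if config.n_lincrnas > 0 else 0
    for j in range(n_decoys):
        if not coding_pos:
            break
        c, s, e = coding_pos[j % len(coding_pos)]
        half = max(1, (e - s) // 2)
        dstart = max(0, s - 1_000)
        dend = min(genome.length(c), s + half)
        if dend <= dstart:
            continue
        candidates.append(Interval(c, dstart, dend, f"DECOY{j + 1:03d}", "lincRNA"))
    return genome, coding, AnnotationTrack("lincRNA_candidates", candidates)


def plant_events(
    config: SimulationConfig,
    genome: GenomeModel,
    lincrna_track: Optional[AnnotationTrack] = None,
) -> TruthSet:
    """Materialize the planted-event truth set.

    Explicit specs are validated (bounds, per-sample non-overlap) and
    classified from their copy states; the diploid heterozygous state
    (CN_t = 2, b = 1) emits no event.  Without explicit specs, each sample
    receives a random number of non-overlapping events with classes drawn
    from a fixed mix.  When ``lincrna_track`` is given, each event records
    the lincRNA genes it overlaps.
    """
    samples = config.sample_ids()
    purities = dict(zip(samples, config.purities()))
    events: Dict[str, List[PlantedEvent]] = {s: [] for s in samples}

    if config.events is not None:
        for spec in config.events:
            if spec.sample not in events:
                raise ValueError(f"event sample {spec.sample!r} not in cohort")
            if spec.end > genome.length(spec.chrom):
                raise ValueError(f"event {spec} exceeds chromosome bounds")
            cls = classify_copy_state(spec.cn_total, spec.cn_b)
            if cls is None:
                continue
            for prev in events[spec.sample]:
                if prev.chrom == spec.chrom and spec.start < prev.end and prev.start < spec.start + (spec.end - spec.start):
                    raise ValueError(
                        f"overlapping event specs for sample {spec.sample}: "
                        f"{prev.chrom}:{prev.start}-{prev.end} vs {spec.chrom}:{spec.start}-{spec.end}"
                    )
            events[spec.sample].append(
                PlantedEvent(spec.chrom, spec.start, spec.end, spec.cn_total, spec.cn_b, cls)
            )
    else:
        rng = _rng(config, stage=2)
        classes = list(EVENT_CLASS_WEIGHTS)
        probs = np.array([EVENT_CLASS_WEIGHTS[c] for c in classes])
        lo, hi = config.events_per_sample
        for sample in samples:
            n_events = int(rng.integers(lo, hi + 1))
            occupied: Dict[str, List[Tuple[int, int]]] = {}
            # log-uniform sizes across the configured spectrum
            for _ in range(n_events):
                cls = classes[int(rng.choice(len(classes), p=probs))]
                size = int(
                    math.exp(
                        rng.uniform(
                            math.log(config.event_length_range[0]),
                            math.log(config.event_length_range[1]),
                        )
                    )
                )
                placed = _place_disjoint(
                    rng, genome.chromosomes, 1, (size, size), occupied
                )
                chrom, start, end = placed[0]
                if cls == "gain":
                    cn_total, cn_b = 3, int(rng.integers(1, 3))
                elif cls == "loss":
                    cn_total, cn_b = 1, int(rng.integers(0, 2))
                elif cls == "homozygous_loss":
                    cn_total, cn_b = 0, 0
                else:  # copy-neutral LOH
                    cn_total, cn_b = 2, int(rng.choice([0, 2]))
                events[sample].append(
                    PlantedEvent(chrom, start, end, cn_total, cn_b, cls)
                )

    if lincrna_track is not None:
        for sample, evs in events.items():
            events[sample] = [
                replace(
                    ev,
                    lincrna_genes=tuple(
                        iv.gene_id
                        for iv in lincrna_track.on(ev.chrom)
                        if min(ev.end, iv.end) > max(ev.start, iv.start)
                    ),
                )
                for ev in evs
            ]
    return TruthSet(
        events={s: tuple(sorted(v, key=lambda e: (e.chrom, e.start))) for s, v in events.items()},
        purity=purities,
    )


def _probe_positions(rng: np.random.Generator, length: int, spacing: float) -> np.ndarray:
    """Jittered probe grid: exponential inter-probe gaps with mean spacing."""
    n_guess = int(length / spacing * 1.3) + 10
    gaps = rng.exponential(spacing, size=n_guess)
    pos = np.cumsum(gaps)
    while pos[-1] < length:
        extra = rng.exponential(spacing, size=n_guess // 2 + 10)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
    pos = pos[pos < length]
    return np.unique(pos.astype(np.int64))


def expected_tumor_lrr(cn_total: float, purity: float, floor: float = -4.0) -> float:
    """Closed-form in-event tumor LRR under the purity mixture model."""
    mix = (1.0 - purity) * 2.0 + purity * cn_total
    if mix <= 0:
        return floor
    return max(floor, math.log2(mix / 2.0))


def expected_tumor_baf(g: int, cn_total: float, cn_b: float, purity: float) -> float:
    """Closed-form in-event tumor BAF for a normal genotype with g B-alleles."""
    b_probe = cn_b if g == 1 else (0.0 if g == 0 else cn_total)
    mix = (1.0 - purity) * 2.0 + purity * cn_total
    if mix <= 0:
        return 0.5
    return ((1.0 - purity) * g + purity * b_probe) / mix


def simulate_probe_signals(
    genome: GenomeModel,
    truth: TruthSet,
    config: SimulationConfig,
) -> Dict[str, Dict[str, List[pd.DataFrame]]]:
    """Generate paired probe-signal tables for every sample.

    Returns ``{sample: {"tumor": [replicate tables], "normal": [...]}}``.
    Probe layout, genotypes and the GC covariate are shared between the two
    members and all replicates of a pair; only the noise differs.
    """
    out: Dict[str, Dict[str, List[pd.DataFrame]]] = {}
    for s_idx, sample in enumerate(truth.samples):
        rng = _rng(config, stage=3, extra=s_idx)
        rho = truth.purity[sample]
        frames: Dict[str, List[pd.DataFrame]] = {"tumor": [], "normal": []}
        chrom_data = []
        for chrom in genome.analysis_names():
            length = genome.length(chrom)
            pos = _probe_positions(rng, length, config.spacing)
            n = pos.size
            u = rng.random(n)
            genotype = np.where(
                u < config.het_rate, "AB",
                np.where(u < config.het_rate + (1 - config.het_rate) / 2, "AA", "BB"),
            )
            genotype = np.where(rng.random(n) < config.nc_rate, "NC", genotype)
            g_count = np.select([genotype == "AA", genotype == "AB"], [0, 1], default=2)
            gc = 0.5 + 0.3 * np.sin(2.0 * math.pi * pos / config.gc_wave_period)
            wave = config.gc_wave_amplitude * (gc - 0.5) / 0.3

            lrr_exp = np.zeros(n)
            baf_exp = g_count / 2.0
            for ev in truth.events[sample]:
                if ev.chrom != chrom:
                    continue
                mask = (pos >= ev.start) & (pos < ev.end)
                lrr_exp[mask] = expected_tumor_lrr(ev.cn_total, rho, config.lrr_floor)
                gm = g_count[mask]
                baf_exp[mask] = [
                    expected_tumor_baf(int(g), ev.cn_total, ev.cn_b, rho) for g in gm
                ]
            names = np.array([f"p_{chrom}_{i:06d}" for i in range(n)])
            chrom_data.append((chrom, names, pos, genotype, g_count, gc, wave, lrr_exp, baf_exp))

        for role in ("tumor", "normal"):
            for _ in range(config.replicates):
                parts = []
                for (chrom, names, pos, genotype, g_count, gc, wave, lrr_exp, baf_exp) in chrom_data:
                    n = pos.size
                    lrr_mean = lrr_exp if role == "tumor" else np.zeros(n)
                    baf_mean = baf_exp if role == "tumor" else g_count / 2.0
                    lrr = lrr_mean + wave + rng.normal(0.0, config.lrr_noise_sd, n)
                    baf = np.clip(baf_mean + rng.normal(0.0, config.baf_noise_sd, n), 0.0, 1.0)
                    if role == "tumor":
                        gt = np.select(
                            [baf < 0.15, baf > 0.85], ["AA", "BB"], default="AB"
                        )
                        gt = np.where(genotype == "NC", "NC", gt)
                    else:
                        gt = genotype
                    parts.append(
                        pd.DataFrame(
                            {
                                "name": names,
                                "chrom": chrom,
                                "pos": pos,
                                "lrr": lrr,
                                "baf": baf,
                                "genotype": gt,
                                "gc": gc,
                            }
                        )
                    )
                frames[role].append(pd.concat(parts, ignore_index=True))
        out[sample] = frames
    return out


def tumor_dosage(event: Optional[PlantedEvent], purity: float, floor: float = 0.01) -> float:
    """Tumor/normal DNA quantity ratio at a locus (1.0 when copy-neutral)."""
    if event is None:
        return 1.0
    mix = (1.0 - purity) * 2.0 + purity * event.cn_total
    return max(mix / 2.0, floor)


def ct_value(quantity: float, efficiency: float, intercept: float) -> float:
    """Noiseless threshold cycle for a starting quantity."""
    if quantity <= 0:
        raise ValueError("quantity must be strictly positive")
    return intercept - math.log10(quantity) / math.log10(1.0 + efficiency)


def simulate_qpcr(
    truth: TruthSet, config: SimulationConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the qPCR experiment implied by the truth set.

    Returns (ct_table, target_map).  The Ct table is tidy with columns
    sample/assay/role/input_ng/replicate/ct: a dilution-series standard per
    assay, both references at copy-neutral dosage for every tumor and
    normal, and one target assay per planted event with the tumor quantity
    scaled by its copy dosage.  ``target_map`` links target assays to their
    events and expected dosage.
    """
    rng = _rng(config, stage=4)
    eff = config.qpcr_efficiency
    icpt = config.qpcr_intercept
    sd = config.qpcr_ct_noise_sd

    def ct(q: float) -> float:
        noise = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
        return ct_value(q, eff, icpt) + noise

    rows: List[dict] = []
    map_rows: List[dict] = []
    assays: List[str] = ["ALPHA_SAT", "ALB"]
    for sample in truth.samples:
        for k, ev in enumerate(truth.events[sample]):
            assay = f"TGT_{sample}_{k + 1}"
            assays.append(assay)
            map_rows.append(
                {
                    "assay": assay,
                    "sample": sample,
                    "chrom": ev.chrom,
                    "start": ev.start,
                    "end": ev.end,
                    "cn_total": ev.cn_total,
                    "event_class": ev.event_class,
                    "expected_dosage": tumor_dosage(ev, truth.purity[sample]),
                }
            )

    for assay in assays:
        for q in config.qpcr_standard_quantities:
            for rep in range(config.qpcr_standard_replicates):
                rows.append(
                    {
                        "sample": "STD",
                        "assay": assay,
                        "role": "standard",
                        "input_ng": q,
                        "replicate": rep + 1,
                        "ct": ct(q),
                    }
                )

    target_map = pd.DataFrame(
        map_rows,
        columns=[
            "assay", "sample", "chrom", "start", "end", "cn_total",
            "event_class", "expected_dosage",
        ],
    )
    for sample in truth.samples:
        dosages = {
            row.assay: row.expected_dosage
            for row in target_map[target_map["sample"] == sample].itertuples()
        }
        for level in config.qpcr_input_levels:
            for rep in range(config.qpcr_input_replicates):
                for ref in ("ALPHA_SAT", "ALB"):
                    for suffix in ("_T", "_N"):
                        rows.append(
                            {
                                "sample": sample + suffix,
                                "assay": ref,
                                "role": "reference",
                                "input_ng": level,
                                "replicate": rep + 1,
                                "ct": ct(level),
                            }
                        )
                for assay, dosage in dosages.items():
                    rows.append(
                        {
                            "sample": sample + "_T",
                            "assay": assay,
                            "role": "target",
                            "input_ng": level,
                            "replicate": rep + 1,
                            "ct": ct(level * dosage),
                        }
                    )
                    rows.append(
                        {
                            "sample": sample + "_N",
                            "assay": assay,
                            "role": "target",
                            "input_ng": level,
                            "replicate": rep + 1,
                            "ct": ct(level),
                        }
                    )
    ct_table = pd.DataFrame(
        rows, columns=["sample", "assay", "role", "input_ng", "replicate", "ct"]
    )
    return ct_table, target_map
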