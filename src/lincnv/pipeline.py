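"""Stage runners binding the modules into the simulate -> call ->
summarize -> qpcr workflow."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as lio
from .annotation import (
    AnnotationTrack,
    aggregate_frequencies,
    build_intergenic_lincrna_reference,
    compartment_percentages,
    intersect_calls_with_track,
)
from .config import PipelineConfig
from .genome import GenomeModel
from .qpcr import call_copy_numbers
from .segmentation import CNVCall, call_cnvs, calls_to_frame
from .signals import (
    combine_replicates,
    filter_probes,
    gc_correct,
    pair_adjust,
    quality_score,
)
from .simulate import (
    TruthSet,
    plant_events,
    simulate_genome,
    simulate_probe_signals,
    simulate_qpcr,
)
from .stats import fold_ratio, linear_fit, wilcoxon_signed_rank

log = logging.getLogger(__name__)


def run_simulate(config: PipelineConfig) -> dict:
    """Generate and write the full synthetic cohort; returns the manifest."""
    out = Path(config.outdir)
    (out / "signals").mkdir(parents=True, exist_ok=True)
    (out / "qpcr").mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    genome, coding, candidates = simulate_genome(sim)
    reference, dropped = build_intergenic_lincrna_reference(candidates, coding)
    truth = plant_events(sim, genome, lincrna_track=reference)
    signals = simulate_probe_signals(genome, truth, sim)
    ct_table, target_map = simulate_qpcr(truth, sim)

    lio.write_genome(genome, out / "genome.tsv")
    lio.write_bed(coding, out / "coding.bed")
    lio.write_bed(candidates, out / "lincrna_candidates.bed")
    lio.write_truth(truth, out / "truth.tsv")
    lio.write_ct_table(ct_table, out / "qpcr" / "ct_table.tsv")
    target_map.to_csv(out / "qpcr" / "targets.tsv", sep="\t", index=False)

    manifest: dict = {
        "seed": sim.seed,
        "genome": "genome.tsv",
        "coding": "coding.bed",
        "lincrna_candidates": "lincrna_candidates.bed",
        "truth": "truth.tsv",
        "ct_table": "qpcr/ct_table.tsv",
        "qpcr_targets": "qpcr/targets.tsv",
        "samples": {},
    }
    for sample, frames in signals.items():
        entry: Dict[str, List[str]] = {"tumor": [], "normal": []}
        for role in ("tumor", "normal"):
            for r, df in enumerate(frames[role], 1):
                rel = f"signals/{sample}_{role}_rep{r}.tsv"
                lio.write_probe_signals(df, out / rel)
                entry[role].append(rel)
        manifest["samples"][sample] = entry
        log.info("sample %s: %d probes x %d replicates per member",
                 sample, len(frames["tumor"][0]), len(frames["tumor"]))
    lio.write_manifest(manifest, out / "manifest.json")
    return manifest


def process_pair(
    tumor_reps: Sequence[pd.DataFrame],
    normal_reps: Sequence[pd.DataFrame],
    gc_correction: bool = True,
) -> pd.DataFrame:
    """Filter, combine, correct and pair one tumor-normal member pair.

    Y-chromosome probes are dropped from both members; no-call genotypes
    are dropped on the normal (whose genotypes define informativeness) and
    the tumor is restricted to the surviving probe set before pairing.
    Each member is GC-corrected on its own wave, then subtracted.
    """
    tumor_reps = [filter_probes(df, drop_no_calls=False) for df in tumor_reps]
    normal_reps = [filter_probes(df, drop_no_calls=True) for df in normal_reps]
    tumor = combine_replicates(tumor_reps)
    normal = combine_replicates(normal_reps)
    # NC filtering may differ between replicates of the normal; re-apply
    normal = filter_probes(normal, drop_no_calls=True)
    keep = set(normal["name"])
    tumor = tumor[tumor["name"].isin(keep)].reset_index(drop=True)
    if gc_correction and "gc" in tumor.columns:
        tumor = gc_correct(tumor, robust=True)
        normal = gc_correct(normal, robust=True)
    return pair_adjust(tumor, normal)


def run_call(config: PipelineConfig) -> Dict[str, List[CNVCall]]:
    """Run calling for every manifest sample; writes SEG files per sample."""
    out = Path(config.outdir)
    manifest = lio.read_manifest(out / "manifest.json")
    (out / "calls").mkdir(exist_ok=True)
    all_calls: Dict[str, List[CNVCall]] = {}
    for sample, entry in manifest["samples"].items():
        for role in ("tumor", "normal"):
            if not entry.get(role):
                raise ValueError(f"sample {sample}: missing {role} member")
        tumor_reps = [lio.read_probe_signals(out / p) for p in entry["tumor"]]
        normal_reps = [lio.read_probe_signals(out / p) for p in entry["normal"]]
        n_raw = len(tumor_reps[0])
        paired = process_pair(tumor_reps, normal_reps, config.gc_correction)
        score = quality_score(paired)
        calls = call_cnvs(paired, config.calling, sample=sample)
        non_neutral = [c for c in calls if c.event_class != "neutral"]
        log.info(
            "sample %s: %d raw probes, %d paired, quality %.4f, %d segments, %d calls",
            sample, n_raw, len(paired), score, len(calls), len(non_neutral),
        )
        lio.write_calls(calls, out / "calls" / f"{sample}.seg.tsv")
        all_calls[sample] = calls
    return all_calls


def _check_summary_invariants(summaries) -> None:
    for s in summaries:
        if s.share_pct:
            total = sum(s.share_pct.values())
            if abs(total - 100.0) > 1e-9:
                raise AssertionError(
                    f"sample {s.sample}: compartment shares sum to {total!r}, not 100"
                )


def run_summarize(config: PipelineConfig) -> dict:
    """Associations, compartment summaries, statistics and Circos tracks."""
    out = Path(config.outdir)
    genome = lio.read_genome(out / "genome.tsv")
    coding = lio.read_bed(out / "coding.bed", "coding")
    candidates = lio.read_bed(out / "lincrna_candidates.bed", "lincrna_candidates")
    for iv in list(coding) + list(candidates):
        if iv.chrom not in genome or iv.end > genome.length(iv.chrom):
            raise ValueError(f"track interval {iv.gene_id} outside genome bounds")
    reference, dropped = build_intergenic_lincrna_reference(candidates, coding)
    lio.write_bed(reference, out / "lincrna_reference.bed")

    manifest = lio.read_manifest(out / "manifest.json")
    calls_by_sample: Dict[str, List[CNVCall]] = {}
    non_neutral: List[CNVCall] = []
    for sample in manifest["samples"]:
        calls = lio.read_calls(out / "calls" / f"{sample}.seg.tsv")
        calls_by_sample[sample] = calls
        non_neutral.extend(c for c in calls if c.event_class != "neutral")

    associations = intersect_calls_with_track(non_neutral, reference)
    associations.to_csv(out / "associations.tsv", sep="\t", index=False)

    summaries, cohort = compartment_percentages(calls_by_sample, coding, reference, genome)
    _check_summary_invariants(summaries)
    rows = []
    for s in summaries:
        row = {
            "sample": s.sample,
            "genic_bp": s.genic_bp,
            "lincrna_bp": s.lincrna_bp,
            "intergenic_bp": s.intergenic_bp,
        }
        for comp in ("genic", "lincrna", "intergenic"):
            row[f"share_{comp}"] = s.share_pct.get(comp, float("nan"))
            row[f"affected_{comp}"] = s.affected_pct.get(comp, float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "compartments.tsv", sep="\t", index=False)

    report: dict = dict(cohort)
    report["n_affected_lincrnas"] = int(associations["gene_id"].nunique()) if len(associations) else 0
    report["n_association_events"] = int(len(associations))
    with_cnv = [s for s in summaries if s.total_bp > 0]
    if len(with_cnv) >= 1:
        genic = [s.share_pct["genic"] for s in with_cnv]
        linc = [s.share_pct["lincrna"] for s in with_cnv]
        diffs = np.array(genic) - np.array(linc)
        if np.any(diffs != 0):
            w = wilcoxon_signed_rank(diffs)
            report["wilcoxon_W"] = w.statistic
            report["wilcoxon_p"] = w.pvalue
        if np.mean(linc) > 0:
            report["genic_vs_lincrna_fold"] = fold_ratio(genic, linc)
        if len(with_cnv) >= 3 and np.ptp(genic) > 0:
            fit = linear_fit(genic, linc)
            report["regression_slope"] = fit.slope
            report["regression_intercept"] = fit.intercept
            report["regression_r2"] = fit.r_squared
    pd.DataFrame([report]).to_csv(out / "cohort_stats.tsv", sep="\t", index=False)

    freqs = aggregate_frequencies(calls_by_sample, genome, config.summarize.bin_size)
    lio.write_circos(freqs, "gain_freq", out / "circos_gains.txt")
    lio.write_circos(freqs, "loss_freq", out / "circos_losses.txt")
    log.info(
        "summarize: %d associations over %d lincRNAs; lincRNA reference %d/%d kept",
        len(associations), report["n_affected_lincrnas"], len(reference), len(candidates),
    )
    return report


def run_qpcr(config: PipelineConfig) -> pd.DataFrame:
    """qPCR quantification and copy-ratio calls; reports truth concordance
    when the simulated target map is present."""
    out = Path(config.outdir)
    ct_table = lio.read_ct_table(out / "qpcr" / "ct_table.tsv")
    results = call_copy_numbers(ct_table, cutoff=config.qpcr.cutoff)

    targets_path = out / "qpcr" / "targets.tsv"
    if targets_path.exists():
        targets = pd.read_csv(targets_path, sep="\t")
        expected = {}
        for row in targets.itertuples():
            if row.expected_dosage < 1.0 - config.qpcr.cutoff:
                expected[row.assay] = "loss"
            elif row.expected_dosage > 1.0 + config.qpcr.cutoff:
                expected[row.assay] = "gain"
            else:
                expected[row.assay] = "normal"
        own_sample = dict(zip(targets["assay"], targets["sample"]))
        mask = [
            own_sample.get(r.target) == r.sample for r in results.itertuples()
        ]
        own = results[np.array(mask, dtype=bool)] if len(results) else results
        if len(own):
            agree = [
                expected.get(r.target) == r.classification for r in own.itertuples()
            ]
            results = results.assign()
            concordance = float(np.mean(agree))
            log.info("qPCR concordance with truth: %.1f%% (%d assays)",
                     100 * concordance, len(own))
            pd.DataFrame(
                [{"n_assays": len(own), "concordance": concordance}]
            ).to_csv(out / "qpcr" / "concordance.tsv", sep="\t", index=False)
    results.to_csv(out / "qpcr" / "qpcr_calls.tsv", sep="\t", index=False)
    return results


def run_all(config: PipelineConfig) -> None:
    run_simulate(config)
    run_call(config)
    run_summarize(config)
    run_qpcr(config)
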