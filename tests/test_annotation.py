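import numpy as np
import pandas as pd
import pytest

from lincnv.annotation import (
    AnnotationTrack,
    Interval,
    aggregate_frequencies,
    build_intergenic_lincrna_reference,
    compartment_percentages,
    dissect_segment,
    genome_compartment_sizes,
    intersect_calls_with_track,
    map_probes_to_track,
    merge_intervals,
)
from lincnv.genome import GenomeModel
from lincnv.segmentation import CNVCall

from conftest import make_probe_frame
from oracles import dissect_by_bases, label_bases, probes_in_intervals


def call(chrom, start, end, cls="loss", sample="S1", n=10):
    return CNVCall(chrom=chrom, start=start, end=end, n_probes=n,
                   mean_lrr=-1.0 if cls != "gain" else 1.0, mean_dev=float("nan"),
                   event_class=cls, sample=sample)


class TestTrackValidation:
    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            Interval("chr1", 100, 100, "X")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            AnnotationTrack("t", [Interval("chr1", 0, 10, "A"), Interval("chr1", 20, 30, "A")])

    def test_merge_handles_overlap_and_abutment(self):
        s, e = merge_intervals(np.array([0, 5, 20]), np.array([10, 15, 25]))
        assert list(s) == [0, 20] and list(e) == [15, 25]


class TestBuildReference:
    def test_disjoint_retained(self):
        coding = AnnotationTrack("c", [Interval("chr1", 100, 300, "G1")])
        cands = AnnotationTrack("l", [Interval("chr1", 500, 600, "L1")])
        ref, dropped = build_intergenic_lincrna_reference(cands, coding)
        assert [iv.gene_id for iv in ref] == ["L1"] and dropped == []

    def test_single_bp_overlap_dropped(self):
        coding = AnnotationTrack("c", [Interval("chr1", 100, 300, "G1")])
        cands = AnnotationTrack("l", [Interval("chr1", 299, 400, "L1")])
        ref, dropped = build_intergenic_lincrna_reference(cands, coding)
        # brute-force per-base check agrees: base 299 is shared
        labels = label_bases(1000, [(100, 300)], [])
        assert labels[299:400].max() == 1
        assert len(ref) == 0 and dropped == ["L1"]

    def test_abutting_half_open_retained(self):
        coding = AnnotationTrack("c", [Interval("chr1", 100, 300, "G1")])
        cands = AnnotationTrack("l", [Interval("chr1", 300, 400, "L1")])
        ref, dropped = build_intergenic_lincrna_reference(cands, coding)
        assert [iv.gene_id for iv in ref] == ["L1"]


class TestMapProbes:
    def test_empty_track(self):
        probes = make_probe_frame([10, 20], [0, 0])
        assign, counts = map_probes_to_track(probes, AnnotationTrack("t", []))
        assert len(assign) == 0 and len(counts) == 0

    def test_half_open_boundaries(self):
        track = AnnotationTrack("t", [Interval("chr1", 100, 200, "G1")])
        probes = make_probe_frame([100, 199, 200], [0, 0, 0])
        assign, _ = map_probes_to_track(probes, track)
        assert sorted(assign["pos"]) == [100, 199]

    def test_overlapping_intervals_count_twice(self):
        track = AnnotationTrack("t", [Interval("chr1", 0, 100, "A"), Interval("chr1", 50, 150, "B")])
        probes = make_probe_frame([75], [0])
        assign, counts = map_probes_to_track(probes, track)
        assert sorted(assign["gene_id"]) == ["A", "B"]
        assert counts["A"] == 1 and counts["B"] == 1

    def test_random_against_point_scan_oracle(self, rng):
        track = AnnotationTrack(
            "t",
            [
                Interval("chr1", 100, 400, "A"),
                Interval("chr1", 350, 700, "B"),
                Interval("chr2", 0, 500, "C"),
            ],
        )
        pos1 = np.sort(rng.choice(1000, 12, replace=False))
        pos2 = np.sort(rng.choice(1000, 8, replace=False))
        probes = pd.concat(
            [make_probe_frame(pos1, np.zeros(12), chrom="chr1"),
             make_probe_frame(pos2, np.zeros(8), chrom="chr2", name_prefix="q")],
            ignore_index=True,
        )
        assign, _ = map_probes_to_track(probes, track)
        oracle = probes_in_intervals(
            list(zip(probes["chrom"], probes["pos"])),
            [(iv.chrom, iv.start, iv.end, iv.gene_id) for iv in track],
        )
        expected = sorted((probes["name"].iloc[i], g) for i, g in oracle)
        assert sorted(zip(assign["name"], assign["gene_id"])) == expected


class TestIntersectCalls:
    def test_full_containment_is_100pct(self):
        track = AnnotationTrack("t", [Interval("chr1", 500, 600, "L1")])
        out = intersect_calls_with_track([call("chr1", 0, 1000)], track)
        assert out["overlap_pct"].iloc[0] == 100.0
        assert out["overlap_bp"].iloc[0] == 100

    def test_partial_overlap(self):
        track = AnnotationTrack("t", [Interval("chr1", 500, 600, "L1")])
        out = intersect_calls_with_track([call("chr1", 550, 600)], track)
        assert out["overlap_bp"].iloc[0] == 50
        assert out["overlap_pct"].iloc[0] == pytest.approx(50.0)

    def test_call_between_genes(self):
        track = AnnotationTrack("t", [Interval("chr1", 0, 100, "A"), Interval("chr1", 900, 1000, "B")])
        out = intersect_calls_with_track([call("chr1", 200, 800)], track)
        assert len(out) == 0

    def test_neutral_calls_ignored(self):
        track = AnnotationTrack("t", [Interval("chr1", 0, 100, "A")])
        out = intersect_calls_with_track([call("chr1", 0, 100, cls="neutral")], track)
        assert len(out) == 0


class TestDissect:
    def test_fully_genic(self):
        coding = AnnotationTrack("c", [Interval("chr1", 0, 1000, "G1")])
        linc = AnnotationTrack("l", [])
        assert dissect_segment(call("chr1", 200, 700), coding, linc) == (500, 0, 0)

    def test_worked_example_full_chromosome(self, toy_tracks):
        coding, linc = toy_tracks
        assert dissect_segment(call("chr1", 0, 1000), coding, linc) == (200, 100, 700)

    def test_worked_example_inner_window(self, toy_tracks):
        coding, linc = toy_tracks
        assert dissect_segment(call("chr1", 250, 550), coding, linc) == (50, 50, 200)

    def test_matches_per_base_oracle(self, toy_tracks, rng):
        coding, linc = toy_tracks
        labels = label_bases(1000, [(100, 300)], [(500, 600)])
        for _ in range(25):
            s = int(rng.integers(0, 990))
            e = int(rng.integers(s + 1, 1001))
            assert dissect_segment(call("chr1", s, e), coding, linc) == dissect_by_bases(s, e, labels)

    def test_conservation(self, toy_tracks, rng):
        coding, linc = toy_tracks
        for _ in range(50):
            s = int(rng.integers(0, 999))
            e = int(rng.integers(s + 1, 1001))
            g, l, o = dissect_segment(call("chr1", s, e), coding, linc)
            assert g + l + o == e - s and min(g, l, o) >= 0

    def test_overlapping_coding_genes_counted_once(self):
        coding = AnnotationTrack(
            "c", [Interval("chr1", 100, 300, "G1"), Interval("chr1", 200, 400, "G2")]
        )
        linc = AnnotationTrack("l", [])
        assert dissect_segment(call("chr1", 0, 1000), coding, linc) == (300, 0, 700)

    def test_corrupt_overlap_rejected(self):
        coding = AnnotationTrack("c", [Interval("chr1", 100, 300, "G1")])
        linc = AnnotationTrack("l", [Interval("chr1", 250, 350, "L1")])
        with pytest.raises(ValueError, match="overlap"):
            dissect_segment(call("chr1", 0, 1000), coding, linc)


class TestCompartmentPercentages:
    def test_single_fully_genic_call(self, toy_genome):
        coding = AnnotationTrack("c", [Interval("chr1", 100, 300, "G1")])
        linc = AnnotationTrack("l", [Interval("chr1", 500, 600, "L1")])
        summaries, cohort = compartment_percentages(
            {"S1": [call("chr1", 100, 300)]}, coding, linc, toy_genome
        )
        assert summaries[0].share_pct == {"genic": 100.0, "lincrna": 0.0, "intergenic": 0.0}

    def test_two_equal_calls_split_50_50(self, toy_genome):
        coding = AnnotationTrack("c", [Interval("chr1", 0, 100, "G1")])
        linc = AnnotationTrack("l", [Interval("chr1", 500, 600, "L1")])
        calls = [call("chr1", 0, 100), call("chr1", 500, 600)]
        summaries, _ = compartment_percentages({"S1": calls}, coding, linc, toy_genome)
        s = summaries[0].share_pct
        assert s["genic"] == pytest.approx(50.0) and s["lincrna"] == pytest.approx(50.0)

    def test_three_sample_hand_computed_means(self, toy_genome):
        coding = AnnotationTrack("c", [Interval("chr1", 0, 200, "G1")])
        linc = AnnotationTrack("l", [Interval("chr1", 500, 600, "L1")])
        calls = {
            "S1": [call("chr1", 0, 200)],                       # 100% genic
            "S2": [call("chr1", 500, 600)],                     # 100% lincRNA
            "S3": [call("chr1", 0, 400)],                       # 50% genic, 50% intergenic
        }
        summaries, cohort = compartment_percentages(calls, coding, linc, toy_genome)
        # hand-computed spreadsheet-style means over the three samples
        assert cohort["mean_share_genic"] == pytest.approx((100 + 0 + 50) / 3)
        assert cohort["mean_share_lincrna"] == pytest.approx(100 / 3)
        assert cohort["mean_share_intergenic"] == pytest.approx(50 / 3)
        assert cohort["genic_vs_lincrna_fold"] == pytest.approx(1.5)

    def test_zero_cnv_sample_has_no_shares(self, toy_genome):
        coding = AnnotationTrack("c", [Interval("chr1", 0, 100, "G1")])
        linc = AnnotationTrack("l", [])
        summaries, cohort = compartment_percentages({"S1": []}, coding, linc, toy_genome)
        assert summaries[0].share_pct == {}
        assert cohort["n_with_cnv"] == 0

    def test_affected_fraction_of_compartments(self, toy_genome):
        coding = AnnotationTrack("c", [Interval("chr1", 0, 100, "G1")])
        linc = AnnotationTrack("l", [Interval("chr1", 500, 600, "L1")])
        summaries, _ = compartment_percentages(
            {"S1": [call("chr1", 0, 50)]}, coding, linc, toy_genome
        )
        sizes = genome_compartment_sizes(coding, linc, toy_genome)
        assert sizes == {"genic": 100, "lincrna": 100, "intergenic": 2800}
        assert summaries[0].affected_pct["genic"] == pytest.approx(50.0)
        assert summaries[0].affected_pct["lincrna"] == 0.0


class TestAggregateFrequencies:
    def test_no_calls_all_zero(self, toy_genome):
        out = aggregate_frequencies({f"S{i}": [] for i in range(7)}, toy_genome, 500)
        assert (out["gain_freq"] == 0).all() and (out["loss_freq"] == 0).all()

    def test_one_of_seven(self, toy_genome):
        calls = {f"S{i}": [] for i in range(1, 8)}
        calls["S1"] = [call("chr1", 0, 400)]
        out = aggregate_frequencies(calls, toy_genome, 500)
        first = out[(out["chrom"] == "chr1") & (out["start"] == 0)]
        assert first["loss_freq"].iloc[0] == pytest.approx(1 / 7)

    def test_recurrent_in_all(self, toy_genome):
        calls = {f"S{i}": [call("chr1", 0, 400, cls="gain")] for i in range(1, 8)}
        out = aggregate_frequencies(calls, toy_genome, 500)
        assert out[(out["chrom"] == "chr1") & (out["start"] == 0)]["gain_freq"].iloc[0] == 1.0

    def test_frequencies_on_lattice(self, toy_genome, rng):
        calls = {}
        for i in range(1, 6):
            evs = []
            if rng.random() < 0.7:
                s = int(rng.integers(0, 900))
                evs.append(call("chr1", s, s + 100, cls=rng.choice(["gain", "loss", "homozygous_loss"])))
            calls[f"S{i}"] = evs
        out = aggregate_frequencies(calls, toy_genome, 250)
        lattice = {k / 5 for k in range(6)}
        assert set(out["gain_freq"]).issubset(lattice)
        assert set(out["loss_freq"]).issubset(lattice)
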