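import math

import numpy as np
import pandas as pd
import pytest

from lincnv.annotation import build_intergenic_lincrna_reference
from lincnv.signals import pair_adjust
from lincnv.simulate import (
    EventSpec,
    SimulationConfig,
    TruthSet,
    classify_copy_state,
    ct_value,
    expected_tumor_baf,
    expected_tumor_lrr,
    plant_events,
    simulate_genome,
    simulate_probe_signals,
    simulate_qpcr,
)

from oracles import pairwise_overlaps

SMALL = dict(
    n_pairs=1,
    chrom_lengths={"chr1": 10_000_000},
    n_coding_genes=10,
    n_lincrnas=5,
    replicates=1,
)


class TestSimulateGenome:
    def test_zero_lincrnas(self):
        cfg = SimulationConfig(seed=1, **{**SMALL, "n_lincrnas": 0})
        genome, coding, cands = simulate_genome(cfg)
        assert len(cands) == 0 and len(coding) > 0

    def test_determinism_under_seed(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        a = simulate_genome(cfg)
        b = simulate_genome(cfg)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_disjoint_placement_brute_force(self):
        cfg = SimulationConfig(seed=2, **{**SMALL, "n_decoy_lincrnas": 0})
        genome, coding, linc = simulate_genome(cfg)
        ivs = [(iv.chrom, iv.start, iv.end) for iv in list(coding) + list(linc)]
        assert len(ivs) == 15
        assert pairwise_overlaps(ivs) == []  # O(n^2) oracle
        for iv in list(coding) + list(linc):
            assert 0 <= iv.start < iv.end <= genome.length(iv.chrom)

    def test_decoys_overlap_coding(self):
        cfg = SimulationConfig(seed=3, **{**SMALL, "n_decoy_lincrnas": 2})
        _, coding, cands = simulate_genome(cfg)
        ref, dropped = build_intergenic_lincrna_reference(cands, coding)
        assert sorted(dropped) == ["DECOY001", "DECOY002"]

    def test_unfittable_request_fails(self):
        cfg = SimulationConfig(
            seed=1, n_pairs=1, chrom_lengths={"chr1": 50_000},
            n_coding_genes=500, n_lincrnas=0, coding_length_range=(20_000, 30_000),
        )
        with pytest.raises(ValueError, match="place"):
            simulate_genome(cfg)


class TestPlantEvents:
    def genome(self, cfg):
        return simulate_genome(cfg)[0]

    def test_diploid_het_state_emits_nothing(self):
        cfg = SimulationConfig(
            seed=1, **SMALL,
            events=(EventSpec("S1", "chr1", 1000, 2000, 2, 1),),
        )
        truth = plant_events(cfg, self.genome(cfg))
        assert truth.events["S1"] == ()

    def test_copy_state_classes(self):
        assert classify_copy_state(0, 0) == "homozygous_loss"
        assert classify_copy_state(2, 0) == "allelic_imbalance"
        assert classify_copy_state(2, 2) == "allelic_imbalance"
        assert classify_copy_state(3, 1) == "gain"
        assert classify_copy_state(1, 0) == "loss"
        assert classify_copy_state(2, 1) is None

    def test_overlapping_specs_rejected(self):
        cfg = SimulationConfig(
            seed=1, **SMALL,
            events=(
                EventSpec("S1", "chr1", 1000, 5000, 1, 0),
                EventSpec("S1", "chr1", 4000, 9000, 3, 2),
            ),
        )
        with pytest.raises(ValueError, match="overlap"):
            plant_events(cfg, self.genome(cfg))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            SimulationConfig(
                seed=1, **SMALL,
                events=(EventSpec("S1", "chr1", 0, 20_000_000, 1, 0),),
            )

    def test_auto_events_non_overlapping_per_sample(self):
        cfg = SimulationConfig(seed=9, **{**SMALL, "n_pairs": 3})
        truth = plant_events(cfg, self.genome(cfg))
        for sample, events in truth.events.items():
            ivs = [(e.chrom, e.start, e.end) for e in events]
            assert pairwise_overlaps(ivs) == []

    def test_lincrna_overlap_annotation(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        genome, coding, cands = simulate_genome(cfg)
        ref, _ = build_intergenic_lincrna_reference(cands, coding)
        iv = ref.intervals[0]
        cfg2 = SimulationConfig(
            seed=4, **SMALL,
            events=(EventSpec("S1", iv.chrom, max(0, iv.start - 100), iv.end + 100, 1, 0),),
        )
        truth = plant_events(cfg2, genome, lincrna_track=ref)
        assert iv.gene_id in truth.events["S1"][0].lincrna_genes


class TestSignalModel:
    @pytest.mark.parametrize(
        "purity,cn,expected",
        [
            (1.0, 1, -1.0),
            (0.5, 1, math.log2(0.75)),  # ~= -0.415
            (1.0, 3, math.log2(1.5)),
            (1.0, 2, 0.0),
        ],
    )
    def test_expected_lrr(self, purity, cn, expected):
        assert expected_tumor_lrr(cn, purity) == pytest.approx(expected)

    def test_expected_lrr_floor_for_homozygous_loss(self):
        assert expected_tumor_lrr(0, 1.0, floor=-4.0) == -4.0

    def test_expected_baf_loh(self):
        # rho=1, CN_t=2, b=0, AB normal (g=1) -> tumor BAF 0
        assert expected_tumor_baf(1, 2, 0, 1.0) == 0.0
        assert expected_tumor_baf(1, 2, 2, 1.0) == 1.0
        assert expected_tumor_baf(0, 2, 0, 1.0) == 0.0
        assert expected_tumor_baf(2, 3, 1, 1.0) == pytest.approx(1.0)

    def zero_noise_config(self, events, purity=1.0):
        return SimulationConfig(
            seed=11, n_pairs=1, chrom_lengths={"chr1": 3_000_000},
            n_coding_genes=4, n_lincrnas=2, replicates=1,
            lrr_noise_sd=0.0, baf_noise_sd=0.0, gc_wave_amplitude=0.0,
            nc_rate=0.0, purity=purity, events=events,
        )

    def test_zero_noise_paired_lrr_matches_closed_form(self):
        for purity, cn in [(1.0, 1), (0.5, 1), (1.0, 3), (0.7, 3)]:
            cfg = self.zero_noise_config(
                (EventSpec("S1", "chr1", 1_000_000, 2_000_000, cn, min(1, cn)),),
                purity=purity,
            )
            genome, _, _ = simulate_genome(cfg)
            truth = plant_events(cfg, genome)
            sig = simulate_probe_signals(genome, truth, cfg)["S1"]
            paired = pair_adjust(sig["tumor"][0], sig["normal"][0])
            inside = paired[(paired["pos"] >= 1_000_000) & (paired["pos"] < 2_000_000)]
            expected = expected_tumor_lrr(cn, purity)
            assert abs(inside["lrr"].mean() - expected) <= 1e-9
            outside = paired[paired["pos"] < 1_000_000]
            assert abs(outside["lrr"].mean()) <= 1e-9

    def test_zero_noise_tumor_baf_matches_closed_form(self):
        cfg = self.zero_noise_config(
            (EventSpec("S1", "chr1", 1_000_000, 2_000_000, 2, 0),), purity=0.6
        )
        genome, _, _ = simulate_genome(cfg)
        truth = plant_events(cfg, genome)
        tumor = simulate_probe_signals(genome, truth, cfg)["S1"]["tumor"][0]
        normal = simulate_probe_signals(genome, truth, cfg)["S1"]["normal"][0]
        inside = (tumor["pos"] >= 1_000_000) & (tumor["pos"] < 2_000_000)
        het = normal["genotype"] == "AB"
        got = tumor.loc[inside & het, "baf"].to_numpy()
        np.testing.assert_allclose(got, expected_tumor_baf(1, 2, 0, 0.6), atol=1e-12)

    def test_baf_bounded(self):
        cfg = SimulationConfig(seed=13, **SMALL, baf_noise_sd=0.3)
        genome, _, _ = simulate_genome(cfg)
        truth = plant_events(cfg, genome)
        for role_frames in simulate_probe_signals(genome, truth, cfg)["S1"].values():
            for df in role_frames:
                assert df["baf"].between(0.0, 1.0).all()

    def test_probe_spacing_roughly_exponential(self):
        cfg = SimulationConfig(seed=14, **SMALL, spacing=700.0)
        genome, _, _ = simulate_genome(cfg)
        truth = plant_events(cfg, genome)
        df = simulate_probe_signals(genome, truth, cfg)["S1"]["normal"][0]
        gaps = np.diff(np.sort(df["pos"].to_numpy()))
        assert gaps.mean() == pytest.approx(700, rel=0.05)

    def test_byte_identical_reruns(self):
        cfg = SimulationConfig(seed=15, **SMALL)
        genome, _, _ = simulate_genome(cfg)
        truth = plant_events(cfg, genome)
        a = simulate_probe_signals(genome, truth, cfg)
        b = simulate_probe_signals(genome, truth, cfg)
        pd.testing.assert_frame_equal(a["S1"]["tumor"][0], b["S1"]["tumor"][0])
        pd.testing.assert_frame_equal(a["S1"]["normal"][0], b["S1"]["normal"][0])

    def test_replicates_share_layout_differ_in_noise(self):
        cfg = SimulationConfig(seed=16, **{**SMALL, "replicates": 2})
        genome, _, _ = simulate_genome(cfg)
        truth = plant_events(cfg, genome)
        reps = simulate_probe_signals(genome, truth, cfg)["S1"]["tumor"]
        assert (reps[0]["pos"] == reps[1]["pos"]).all()
        assert not np.allclose(reps[0]["lrr"], reps[1]["lrr"])


class TestSimulateQpcr:
    def truth(self):
        return TruthSet(events={"S1": ()}, purity={"S1": 1.0})

    def test_twofold_dilution_one_cycle_at_full_efficiency(self):
        assert ct_value(2.0, 1.0, 30.0) - ct_value(4.0, 1.0, 30.0) == pytest.approx(-(-1.0))
        assert ct_value(1.0, 1.0, 30.0) - ct_value(2.0, 1.0, 30.0) == pytest.approx(1.0)

    def test_tenfold_dilution(self):
        diff = ct_value(1.0, 1.0, 30.0) - ct_value(10.0, 1.0, 30.0)
        assert diff == pytest.approx(math.log2(10))  # ~= 3.322

    def test_nonpositive_quantity_rejected(self):
        with pytest.raises(ValueError):
            ct_value(0.0, 1.0, 30.0)

    def test_deterministic_reruns(self):
        cfg = SimulationConfig(seed=21, n_pairs=1)
        a, _ = simulate_qpcr(self.truth(), cfg)
        b, _ = simulate_qpcr(self.truth(), cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_matches_closed_form(self):
        cfg = SimulationConfig(seed=22, n_pairs=1, qpcr_ct_noise_sd=0.0)
        table, _ = simulate_qpcr(self.truth(), cfg)
        std = table[(table["role"] == "standard") & (table["assay"] == "ALB")]
        for row in std.itertuples():
            assert row.ct == pytest.approx(
                ct_value(row.input_ng, cfg.qpcr_efficiency, cfg.qpcr_intercept)
            )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"spacing": 0.0},
            {"lrr_noise_sd": -0.1},
            {"purity": 0.0},
            {"purity": 1.5},
            {"replicates": 0},
            {"qpcr_efficiency": 0.0},
            {"n_pairs": 0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, **{**{k: v for k, v in SMALL.items() if k not in kwargs}, **kwargs})
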