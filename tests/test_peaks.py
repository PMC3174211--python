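"""Sliding-window detector: scores, empirical null, merging, FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_window_scores, make_track
from pioneerchip import motifs as mo
from pioneerchip import peaks as pk
from pioneerchip import simulate as sim


def wide_params(n_probes, **kw):
    """Window wide enough that every probe's window holds the full track."""
    return pk.PeakCallParams(w=10 * 24 * n_probes, min_probes=n_probes, **kw)


class TestWindowScores:
    def test_zero_input_gives_zero_scores(self):
        track = make_track(np.zeros(10))
        ws = pk.compute_window_scores(track, wide_params(10))
        assert np.all(ws.t == 0.0)

    def test_constant_track_t_is_sqrt_n_times_c(self):
        # trimmed mean of constants is the constant; sqrt(9) = 3
        for trim in (0.0, 0.1, 0.2):
            track = make_track(np.full(9, 2.5))
            ws = pk.compute_window_scores(track, wide_params(9, trim_fraction=trim))
            assert np.allclose(ws.t, 3 * 2.5)

    def test_trimming_discards_outlier(self):
        # hand enumeration: drop the 0 and the 100, mean of eight 1s = 1
        track = make_track([0, 1, 1, 1, 1, 1, 1, 1, 1, 100])
        ws = pk.compute_window_scores(track, wide_params(10, trim_fraction=0.10))
        assert np.allclose(ws.t, math.sqrt(10))

    def test_windows_below_min_probes_dropped(self):
        track = make_track(np.ones(6))
        ws = pk.compute_window_scores(track, pk.PeakCallParams(w=60, min_probes=5))
        # w=60 spans at most 3 probes at 24-bp spacing
        assert len(ws) == 0

    def test_empty_track_empty_result(self):
        track = pk.ProbeTrack("chr1", np.empty(0, int), np.empty(0, int), np.empty(0))
        assert len(pk.compute_window_scores(track, pk.PeakCallParams())) == 0

    def test_agrees_with_brute_force_oracle(self, small_noise_config):
        track = sim.simulate_probe_track(small_noise_config, pk.CHIP_VS_IGG)
        assert len(track) <= 900
        for params in (pk.PeakCallParams(), pk.PeakCallParams(w=240, trim_fraction=0.0),
                       pk.PeakCallParams(w=777, trim_fraction=0.25, min_probes=3)):
            ws = pk.compute_window_scores(track, params)
            oracle = brute_force_window_scores(track, params)
            assert len(ws) == len(oracle)
            for i, (center, n, t) in enumerate(oracle):
                assert ws.centers[i] == center
                assert ws.n[i] == n
                assert ws.t[i] == pytest.approx(t, rel=1e-12)


class TestEmpiricalNull:
    def scores(self, ts):
        ts = np.asarray(ts, dtype=float)
        z = np.zeros(len(ts), dtype=np.int64)
        return pk.WindowScores(z, z, z + 1, z + 5, ts)

    def test_null_from_negative_tail(self):
        null = pk.estimate_empirical_null(self.scores([-2, -1, 1, 2]))
        assert np.array_equal(null.magnitudes, [1.0, 2.0])
        assert null.m == 4 and not null.degenerate

    def test_all_positive_scores_degenerate(self, caplog):
        null = pk.estimate_empirical_null(self.scores([1, 2, 3]))
        assert null.degenerate
        assert pk.assign_pvalue(5.0, null) == pytest.approx(1 / 4)

    def test_pvalue_enumeration(self):
        null = pk.estimate_empirical_null(self.scores([-2, -1, 1, 2]))
        assert pk.assign_pvalue(2.0, null) == pytest.approx((1 + 1) / (1 + 4))
        assert pk.assign_pvalue(0.5, null) == pytest.approx((1 + 2) / (1 + 4))
        assert pk.assign_pvalue(0.0, null) == 1.0
        assert pk.assign_pvalue(-1.0, null) == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=50),
           st.lists(st.floats(0.01, 10), min_size=2, max_size=10))
    def test_pvalue_monotone_nonincreasing_in_t(self, ts, queries):
        if not any(t < 0 for t in ts):
            ts = ts + [-1.0]
        null = pk.estimate_empirical_null(self.scores(ts))
        q = np.sort(np.asarray(queries))
        p = pk.assign_pvalue(q, null)
        assert np.all(np.diff(p) <= 1e-15)

    def test_calibration_on_symmetric_noise(self):
        # positive-score p-values are uniform over their attainable range
        cfg = sim.SimulationConfig(genome_length=500_000, seed=3, spikes=[])
        track = sim.simulate_probe_track(cfg, pk.CHIP_VS_IGG)
        ws = pk.compute_window_scores(track, pk.PeakCallParams())
        null = pk.estimate_empirical_null(ws)
        frac, d = pk.null_calibration(ws, null, alpha=0.01)
        assert d < 0.05
        # the mirrored null is self-calibrating: the overall fraction of
        # windows below alpha tracks alpha itself
        assert frac == pytest.approx(0.01, rel=0.3)


def strong_null():
    # large M so any positive score with zero null exceedances is significant
    return pk.NullModel(magnitudes=np.array([1.0]), m=100_000)


def windows(spans, ts):
    spans = np.asarray(spans)
    return pk.WindowScores(centers=spans.mean(axis=1).astype(np.int64),
                           starts=spans[:, 0], ends=spans[:, 1],
                           n=np.full(len(spans), 5), t=np.asarray(ts, dtype=float))


class TestMerging:
    def test_singleton_region_equals_window_span(self):
        regions = pk.merge_significant_windows(windows([[100, 500]], [5.0]),
                                               strong_null(), pk.PeakCallParams())
        assert (regions[0].start, regions[0].end) == (100, 500)

    def test_gap_below_g_merges(self):
        regions = pk.merge_significant_windows(
            windows([[100, 500], [550, 950]], [5.0, 6.0]),
            strong_null(), pk.PeakCallParams(g=100))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (100, 950)
        assert regions[0].best_t == 6.0

    def test_gap_at_or_above_g_stays_split(self):
        regions = pk.merge_significant_windows(
            windows([[100, 500], [650, 1050]], [5.0, 6.0]),
            strong_null(), pk.PeakCallParams(g=100))
        assert len(regions) == 2

    def test_insignificant_windows_excluded(self):
        null = pk.NullModel(magnitudes=np.array([4.0, 5.0]), m=4)
        regions = pk.merge_significant_windows(windows([[0, 400]], [3.0]), null,
                                               pk.PeakCallParams())
        assert regions == []

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.integers(0, 5000), min_size=1, max_size=30))
    def test_regions_disjoint_and_g_apart(self, starts):
        spans = [[s, s + 400] for s in sorted(starts)]
        regions = pk.merge_significant_windows(
            windows(spans, [5.0] * len(spans)), strong_null(), pk.PeakCallParams(g=100))
        for a, b in zip(regions, regions[1:]):
            assert b.start - a.end >= 100


class TestCallRegions:
    def spiked_config(self, channels, seed=11):
        # min attainable p is 1/(M+1): alpha=1e-4 needs > 1e4 windows
        cfg = sim.SimulationConfig(genome_length=600_000, seed=seed)
        cfg.spikes = [sim.SpikeSpec(center=300_000, half_width=300, height=3.0,
                                    channels=frozenset(channels))]
        return cfg

    def test_either_rule_reports_single_channel_hit(self):
        cfg = self.spiked_config({pk.CHIP_VS_INPUT})
        tracks = {ch: sim.simulate_probe_track(cfg, ch) for ch in pk.CHIP_CHANNELS}
        regions = pk.call_regions(tracks, pk.PeakCallParams())
        hits = [r for r in regions if r.start < 300_300 and r.end > 299_700]
        assert len(hits) == 1
        assert hits[0].sources == frozenset({pk.CHIP_VS_INPUT})

    def test_identical_tracks_match_single_track_call(self):
        cfg = self.spiked_config({pk.CHIP_VS_IGG, pk.CHIP_VS_INPUT})
        track = sim.simulate_probe_track(cfg, pk.CHIP_VS_IGG)
        params = pk.PeakCallParams()
        both = pk.call_regions({pk.CHIP_VS_IGG: track, pk.CHIP_VS_INPUT: track}, params)
        single = pk.call_regions_single(track, params, source=pk.CHIP_VS_IGG)
        assert [(r.start, r.end, r.best_t) for r in both] == \
               [(r.start, r.end, r.best_t) for r in single]
        assert all(r.sources == frozenset(pk.CHIP_CHANNELS) for r in both)

    def test_disjoint_spikes_add_up(self):
        cfg = sim.SimulationConfig(genome_length=600_000, seed=5)
        cfg.spikes = [
            sim.SpikeSpec(center=150_000, half_width=300, height=3.0,
                          channels=frozenset({pk.CHIP_VS_IGG})),
            sim.SpikeSpec(center=450_000, half_width=300, height=3.0,
                          channels=frozenset({pk.CHIP_VS_INPUT})),
        ]
        tracks = {ch: sim.simulate_probe_track(cfg, ch) for ch in pk.CHIP_CHANNELS}
        params = pk.PeakCallParams()
        merged = pk.call_regions(tracks, params)
        n_separate = sum(len(pk.call_regions_single(tracks[ch], params))
                         for ch in pk.CHIP_CHANNELS)
        assert len(merged) == n_separate
        for center, channel in ((150_000, pk.CHIP_VS_IGG), (450_000, pk.CHIP_VS_INPUT)):
            hit = [r for r in merged if r.start <= center < r.end]
            assert len(hit) == 1
            assert hit[0].sources == frozenset({channel})

    def test_missing_both_chip_tracks_rejected(self):
        with pytest.raises(ValueError, match="ChIP comparison"):
            pk.call_regions({}, pk.PeakCallParams())


class TestFdr:
    def test_zero_control_regions_zero_fdr(self):
        cfg = sim.SimulationConfig(genome_length=20_000, seed=2, spikes=[])
        control = sim.simulate_probe_track(cfg, pk.IGG_VS_INPUT)
        est = pk.estimate_fdr_from_control(100, control, pk.PeakCallParams())
        if est.n_control_regions == 0:
            assert est.fdr == 0.0
        assert est.fdr == est.n_control_regions / 100

    def test_ratio_definition_and_clamp(self):
        cfg = sim.SimulationConfig(genome_length=400_000, seed=4)
        cfg.spikes = [sim.SpikeSpec(center=c, half_width=300, height=4.0,
                                    channels=frozenset({pk.IGG_VS_INPUT}))
                      for c in range(20_000, 400_000, 25_000)]
        control = sim.simulate_probe_track(cfg, pk.IGG_VS_INPUT)
        est = pk.estimate_fdr_from_control(100, control, pk.PeakCallParams())
        assert est.n_control_regions >= 15
        assert est.fdr == pytest.approx(min(1.0, est.n_control_regions / 100))
        clamped = pk.estimate_fdr_from_control(1, control, pk.PeakCallParams())
        assert clamped.fdr == 1.0

    def test_zero_chip_regions_undefined(self):
        cfg = sim.SimulationConfig(genome_length=20_000, seed=2, spikes=[])
        control = sim.simulate_probe_track(cfg, pk.IGG_VS_INPUT)
        est = pk.estimate_fdr_from_control(0, control, pk.PeakCallParams())
        assert not est.defined and math.isnan(est.fdr)

    def test_null_only_channels_fdr_near_one(self):
        # noise-only chip and control channels call similar region counts
        n_chip = n_control = 0
        params = pk.PeakCallParams()
        for seed in range(20):
            cfg = sim.SimulationConfig(genome_length=600_000, seed=seed, spikes=[])
            chip = sim.simulate_probe_track(cfg, pk.CHIP_VS_IGG)
            control = sim.simulate_probe_track(cfg, pk.IGG_VS_INPUT)
            n_chip += len(pk.call_regions_single(chip, params))
            n_control += len(pk.call_regions_single(control, params))
        assert n_chip > 0 and n_control > 0
        assert 0.5 <= n_control / n_chip <= 2.0


class TestLocateElement:
    def embed(self, consensus, offsets, length=200, seed=9):
        rng = np.random.default_rng(seed)
        seq = list(rng.choice(list("ACGT"), size=length))
        for k in offsets:
            seq[k:k + len(consensus)] = list(consensus)
        return "".join(seq)

    def test_returns_offset_of_planted_consensus(self):
        pwm = mo.foxa_pwm()
        pwm.threshold = 0.8 * pwm.max_score()
        seq = self.embed(pwm.consensus(), [73])
        offset, fallback = pk.locate_element(seq, pwm)
        assert offset == 73 and not fallback

    def test_no_hit_falls_back_to_midpoint(self):
        pwm = mo.foxa_pwm()
        pwm.threshold = pwm.max_score() + 1.0
        seq = self.embed("A" * pwm.width, [])
        offset, fallback = pk.locate_element(seq, pwm)
        assert offset == len(seq) // 2 and fallback

    def test_tie_breaks_to_leftmost(self):
        pwm = mo.foxa_pwm()
        pwm.threshold = 0.8 * pwm.max_score()
        seq = self.embed(pwm.consensus(), [40, 120])
        offset, fallback = pk.locate_element(seq, pwm)
        assert offset == 40 and not fallback

    def test_sequence_shorter_than_pwm_rejected(self):
        pwm = mo.foxa_pwm()
        with pytest.raises(ValueError, match="shorter"):
            pk.locate_element("ACGT", pwm)
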