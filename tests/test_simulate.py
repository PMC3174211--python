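"""The synthetic generator must reproduce the structure the analysis assumes."""

import numpy as np
import pandas as pd
import pytest

from pioneerchip import activity as act
from pioneerchip import conservation as cons
from pioneerchip import motifs as mo
from pioneerchip import peaks as pk
from pioneerchip import simulate as sim


class TestProbeTrack:
    def test_identical_seed_bit_identical(self):
        cfg = sim.default_config(seed=42)
        a = sim.simulate_probe_track(cfg, pk.CHIP_VS_IGG)
        b = sim.simulate_probe_track(cfg, pk.CHIP_VS_IGG)
        assert np.array_equal(a.values, b.values)
        c = sim.simulate_probe_track(cfg, pk.CHIP_VS_INPUT)
        assert not np.array_equal(a.values, c.values)  # independent channel noise

    def test_noise_moments_match_spec(self):
        cfg = sim.SimulationConfig(genome_length=300_000, seed=1, spikes=[])
        track = sim.simulate_probe_track(cfg, pk.CHIP_VS_IGG)
        n = len(track)
        assert n >= 10_000
        assert abs(track.values.mean()) < 3 * 0.5 / np.sqrt(n)
        assert track.values.std() == pytest.approx(0.5, rel=0.10)

    def test_zero_height_spike_is_noise_identical(self):
        cfg = sim.SimulationConfig(genome_length=50_000, seed=2, spikes=[])
        base = sim.simulate_probe_track(cfg, pk.CHIP_VS_IGG)
        cfg.spikes = [sim.SpikeSpec(center=25_000, half_width=500, height=0.0)]
        spiked = sim.simulate_probe_track(cfg, pk.CHIP_VS_IGG)
        assert np.array_equal(base.values, spiked.values)

    def test_spike_shifts_mean_by_height(self):
        c, h = 25_000, 500
        cfg = sim.SimulationConfig(genome_length=50_000, seed=3,
                                   spikes=[sim.SpikeSpec(center=c, half_width=h, height=2.0)])
        track = sim.simulate_probe_track(cfg, pk.CHIP_VS_IGG)
        mids = track.midpoints
        inside = (mids >= c - h) & (mids < c + h)
        diff = track.values[inside].mean() - track.values[~inside].mean()
        assert diff == pytest.approx(2.0, abs=3 * 0.5 / np.sqrt(inside.sum()))

    def test_spike_absent_from_excluded_channel(self):
        cfg = sim.SimulationConfig(
            genome_length=50_000, seed=4,
            spikes=[sim.SpikeSpec(center=25_000, half_width=500, height=2.0,
                                  channels=frozenset({pk.CHIP_VS_IGG}))])
        control = sim.simulate_probe_track(cfg, pk.IGG_VS_INPUT)
        assert abs(control.values.mean()) < 0.05

    def test_genome_shorter_than_probe_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sim.SimulationConfig(genome_length=40)

    def test_every_spike_overlaps_a_probe(self):
        cfg = sim.default_config(seed=5)
        track = sim.simulate_probe_track(cfg, pk.CHIP_VS_IGG)
        mids = track.midpoints
        for s in cfg.spikes:
            assert np.any((mids >= s.start) & (mids < s.end))


def toy_regions(n):
    return [pk.ChIPRegion("chr1", 1200 * i + 100, 1200 * i + 600, 4.0, 1e-5)
            for i in range(n)]


class TestSequences:
    def test_zero_coprob_leaves_only_primary(self):
        cfg = sim.SimulationConfig(genome_length=10_000, seed=6)
        cfg.motif_embed.co_pwms_active = [(mo.hnf4_pwm(), 0.0)]
        cfg.motif_embed.co_pwms_silent = [(mo.rfx_pwm(), 0.0)]
        _, truth = sim.simulate_sequences(cfg, toy_regions(20), ["active"] * 10 + ["silent"] * 10)
        assert set(truth["role"]) == {"primary"}
        assert len(truth) == 20

    def test_co_motif_count_matches_embed_probability(self):
        # aggregate over seeds: 500 Bernoulli(0.8) placements expected
        n_rfx, n_total = 0, 0
        for seed in range(5, 10):
            cfg = sim.SimulationConfig(genome_length=200_000, seed=seed)
            cfg.motif_embed.co_pwms_silent = [(mo.rfx_pwm(), 0.8)]
            _, truth = sim.simulate_sequences(cfg, toy_regions(100), ["silent"] * 100)
            n_rfx += int((truth["motif"] == "Rfx_syn").sum())
            n_total += 100
        se = np.sqrt(n_total * 0.8 * 0.2)
        assert abs(n_rfx - 0.8 * n_total) <= 3 * se

    def test_placed_instances_score_above_background(self):
        cfg = sim.SimulationConfig(genome_length=50_000, seed=8)
        records, truth = sim.simulate_sequences(cfg, toy_regions(20), ["silent"] * 20)
        seqs = {r.id: str(r.seq) for r in records}
        rng = np.random.default_rng(0)
        bg = "".join(rng.choice(list("ACGT"), size=20_000))
        pwms = {p.name: p for p in [cfg.motif_embed.primary_pwm,
                                    *(p for p, _ in cfg.motif_embed.co_pwms_silent)]}
        for _, row in truth.iterrows():
            pwm = pwms[row["motif"]]
            fwd, rev = mo.scan_all_scores(bg, pwm)
            q95 = np.quantile(np.maximum(fwd, rev), 0.95)
            f, r = mo.scan_all_scores(seqs[row["region"]], pwm)
            assert max(f[row["start"]], r[row["start"]]) > q95

    def test_truth_table_round_trips_inside_sequences(self):
        cfg = sim.SimulationConfig(genome_length=100_000, seed=9)
        records, truth = sim.simulate_sequences(cfg, toy_regions(40),
                                                ["active", "silent"] * 20)
        widths = {p.name: p.width for p in
                  [cfg.motif_embed.primary_pwm,
                   *(p for p, _ in cfg.motif_embed.co_pwms_active),
                   *(p for p, _ in cfg.motif_embed.co_pwms_silent)]}
        for _, row in truth.iterrows():
            assert 0 <= row["start"] <= sim.SEQ_LEN - widths[row["motif"]]

    def test_oversized_embed_window_rejected(self):
        cfg = sim.SimulationConfig(genome_length=10_000, seed=10)
        cfg.motif_embed.embed_window = 600
        with pytest.raises(ValueError, match="embed_window"):
            sim.simulate_sequences(cfg, toy_regions(1), ["active"])

    def test_fasta_output_byte_identical_across_runs(self, tmp_path):
        from pioneerchip import io as io_mod
        cfg = sim.SimulationConfig(genome_length=20_000, seed=11)
        out = []
        for name in ("a.fa", "b.fa"):
            records, _ = sim.simulate_sequences(cfg, toy_regions(5), ["active"] * 5)
            io_mod.write_fasta(records, tmp_path / name)
            out.append((tmp_path / name).read_bytes())
        assert out[0] == out[1]


class TestConservation:
    def test_zero_elevation_no_bound_unbound_difference(self):
        cfg = sim.SimulationConfig(genome_length=100_000, seed=12)
        regions = toy_regions(30)
        track = sim.simulate_conservation(cfg, regions, elevation=0.0)
        bound = [("chr1", r.midpoint) for r in regions[:15]]
        unbound = [("chr1", r.midpoint) for r in regions[15:]]
        res = cons.compare_site_sets(track, bound, unbound, half_width=400, seed=0)
        assert abs(res["difference"]) < 0.02

    def test_elevation_recovered_at_region_centers(self):
        cfg = sim.SimulationConfig(genome_length=200_000, seed=13)
        regions = toy_regions(60)
        track = sim.simulate_conservation(cfg, regions, elevation=0.4)
        bound = [("chr1", r.midpoint) for r in regions]
        rng = np.random.default_rng(1)
        unbound = [("chr1", int(p)) for p in rng.integers(80_000, 195_000, 60)]
        prof_b = cons.average_profile(track, bound, half_width=100)
        prof_u = cons.average_profile(track, unbound, half_width=100)
        # region spans cover +-100 of the center, so the central profile
        # offset carries the full elevation (minus clipping loss at 1)
        assert prof_b.mean.mean() - prof_u.mean.mean() == pytest.approx(0.4, abs=0.05)

    def test_negative_elevation_rejected(self):
        cfg = sim.SimulationConfig(genome_length=10_000, seed=14)
        with pytest.raises(ValueError, match="elevation"):
            sim.simulate_conservation(cfg, [], elevation=-0.1)

    def test_scores_bounded(self):
        cfg = sim.SimulationConfig(genome_length=50_000, seed=15)
        track = sim.simulate_conservation(cfg, toy_regions(10), elevation=0.9)
        arr = track.scores["chr1"]
        assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestExpression:
    def test_delta_ct_identities(self):
        spec = sim.ExpressionSpec()
        table = sim.simulate_expression(spec, seed=16)
        rel = act.delta_ct(table["ct_gene"], table["ct_ref"])
        alb = rel[(table["gene"] == spec.albumin_gene).to_numpy()][0]
        assert alb == pytest.approx(1.0)
        # Ct spacing is exactly -log2 of relative expression
        silent = rel[(table["true_class"] == "silent").to_numpy()]
        assert np.all(silent < 1e-4)

    def test_classifier_recovers_the_56_30_split(self):
        spec = sim.ExpressionSpec(n_active=56, n_silent=30)
        table = sim.simulate_expression(spec, seed=17)
        labels = act.classify_activity(table, spec.albumin_gene)
        assert (labels == "active").sum() == 56
        assert (labels == "silent").sum() == 30

    def test_dynamic_range_spans_five_decades(self):
        table = sim.simulate_expression(sim.ExpressionSpec(), seed=18)
        rel = act.delta_ct(table["ct_gene"], table["ct_ref"])
        assert rel.max() / rel.min() >= 1e5

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            sim.ExpressionSpec(silent_rel_range=(1e-6, 2e-4))
        with pytest.raises(ValueError):
            sim.ExpressionSpec(active_rel_range=(1e-5, 1.0))


class TestIhcCounts:
    def test_zero_mean_fraction_all_unstained(self):
        spec = sim.IhcSpec({"s": sim.IhcStageSpec(8, 0.0, 0.0)})
        counts = sim.simulate_ihc_counts(spec, seed=19)
        assert (counts["stained_nuclei"] == 0).all()

    def test_totals_bounded_300_600(self):
        counts = sim.simulate_ihc_counts(sim.IhcSpec(), seed=20)
        assert counts["total_nuclei"].between(300, 600).all()

    def test_group_mean_tracks_target_fraction(self):
        # normal-tissue stage target 61.6% positive
        spec = sim.IhcSpec({"normal_GEJ": sim.TABLE1_STAGES["normal_GEJ"]})
        counts = sim.simulate_ihc_counts(spec, seed=21)
        pct = 100.0 * counts["stained_nuclei"] / counts["total_nuclei"]
        sem = pct.std(ddof=1) / np.sqrt(len(pct))
        assert abs(pct.mean() - 61.6) <= 3 * max(sem, 3.3)

    def test_determinism(self):
        a = sim.simulate_ihc_counts(sim.IhcSpec(), seed=22)
        b = sim.simulate_ihc_counts(sim.IhcSpec(), seed=22)
        pd.testing.assert_frame_equal(a, b)
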