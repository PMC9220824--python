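import numpy as np
import pandas as pd
import pytest

from isletpulse.doseresponse import four_pl
from isletpulse.synthetic import (
    DEFAULT_TRUTH, GLUCOSE_RAMP_MM, ResponseSimConfig, TraceSimConfig,
    burst_train, dither_on_frames, make_abundance_table, make_genomic_fixture,
    plateau_auc_truth, realized_duty, simulate_dose_points,
    simulate_ramp_traces, simulate_response_segments,
)


class TestDither:
    def test_total_on_frames_match_cumulative_rounding(self):
        for duty in (0.0, 0.037, 0.25, 0.513, 0.9, 1.0):
            n_on = dither_on_frames(duty, 120.0, 6.0, 8)
            assert n_on.sum() == round(duty * 20 * 8)

    def test_per_cycle_counts_within_one_frame_of_target(self):
        n_on = dither_on_frames(0.317, 120.0, 6.0, 10)
        target = 0.317 * 20
        assert set(n_on) <= {int(np.floor(target)), int(np.ceil(target))}

    def test_realized_duty_resolution(self):
        for duty in (0.06, 0.21, 0.47, 0.86):
            r = realized_duty(duty, 120.0, 6.0, 8, skip_cycles=1)
            assert abs(r - duty) <= 1.0 / (20 * 7) + 1e-12


class TestBurstTrain:
    def test_on_and_off_frames_are_saturated(self):
        t = np.arange(0.0, 960.0, 6.0)
        y = burst_train(t, 120.0, 0.4, 6.0, edge_s=2.0)
        n_on = dither_on_frames(0.4, 120.0, 6.0, 8)
        on = np.zeros(len(t), dtype=bool)
        for c, n in enumerate(n_on):
            on[c * 20:c * 20 + n] = True
        assert y[on].min() > 0.8
        assert y[~on].max() < 0.2

    def test_rectangular_mode(self):
        t = np.arange(0.0, 240.0, 6.0)
        y = burst_train(t, 120.0, 0.5, 6.0, edge_s=0.0)
        assert set(np.unique(y)) <= {0.0, 1.0}
        assert y.sum() == 20  # 10 on-frames per 120 s cycle

    def test_full_on_and_full_off(self):
        t = np.arange(0.0, 240.0, 6.0)
        assert np.allclose(burst_train(t, 120.0, 0.0, 6.0), 0.0)
        assert np.allclose(burst_train(t, 120.0, 1.0, 6.0), 1.0, atol=1e-6)


class TestRampSimulator:
    def test_ratio_is_exact_channel_quotient(self, small_ramp):
        _, traces, _ = small_ramp
        ratio = traces.channel("ex500") / traces.channel("ex430")
        pd.testing.assert_frame_equal(ratio, traces.channel("ratio"))

    def test_truth_table_shape_and_range(self, small_ramp):
        config, traces, truth = small_ramp
        n_segments = len(config.segments)
        assert len(truth) == len(traces.rois) * n_segments
        assert truth["true_duty_cycle"].between(0, 1).all()
        assert set(truth["concentration"]) == set(GLUCOSE_RAMP_MM)

    def test_truth_tracks_planted_4pl(self, small_ramp):
        config, _, truth = small_ramp
        for group, params in config.dose_response_truth.items():
            sub = truth[truth.group == group]
            expected = four_pl(sub["concentration"].to_numpy(), *params)
            # realised duty is the dithered waveform's mean over complete
            # cycles: within one on-frame per analysed cycle of the 4PL
            assert np.max(np.abs(sub["true_duty_cycle"] - np.clip(expected, 0, 1))) <= 1 / 140 + 1e-12

    def test_infrared_separates_groups(self, small_ramp):
        _, traces, _ = small_ramp
        ir = traces.channel("infrared").median(axis=0)
        groups = traces.metadata["group_of"]
        lo = [ir[r] for r in traces.rois if groups[r] == "control"]
        hi = [ir[r] for r in traces.rois if groups[r] == "knockout"]
        assert max(lo) < min(hi)

    def test_seed_reproducibility(self):
        cfg = TraceSimConfig(seed=5, n_islets_per_group=2, n_animals_per_group=1)
        t1, u1 = simulate_ramp_traces(cfg)
        t2, u2 = simulate_ramp_traces(cfg)
        pd.testing.assert_frame_equal(t1.channel("ratio"), t2.channel("ratio"))
        pd.testing.assert_frame_equal(u1, u2)


class TestResponseSimulator:
    def test_noise_free_trapezoid_matches_analytic_truth(self):
        cfg = ResponseSimConfig(seed=0, n_islets_per_group=2, noise_sd=0.0)
        traces, truth = simulate_response_segments(cfg)
        t = traces.time
        data = traces.channel("ratio")
        starts = np.cumsum([0.0] + [s.duration for s in cfg.segments])
        for seg, t0 in zip(cfg.segments, starts):
            mask = (t >= t0) & (t < t0 + seg.duration)
            for roi in traces.rois:
                est = np.trapezoid(
                    data[roi].to_numpy()[mask] - cfg.baseline, t[mask]
                )
                row = truth[(truth.roi == roi) & (truth.segment == seg.label)]
                # trapezoid curvature error on exp rise, tau=30s, dt=6s
                assert est == pytest.approx(float(row.true_auc.iloc[0]), abs=0.5)

    def test_plateau_auc_closed_form_limits(self):
        assert plateau_auc_truth(2.0, 100.0, rise_tau=0.0) == 200.0
        # tau -> 0 recovers the rectangle; large span dominated by A*span
        approx = plateau_auc_truth(2.0, 1e5, rise_tau=30.0)
        assert approx == pytest.approx(2.0 * (1e5 - 30.0), rel=1e-6)


class TestDosePoints:
    def test_zero_noise_points_lie_on_curve(self):
        df = simulate_dose_points(DEFAULT_TRUTH, noise_sd=0.0, seed=1)
        for group, params in DEFAULT_TRUTH.items():
            sub = df[df.group == group]
            expected = np.clip(four_pl(sub["concentration"].to_numpy(), *params), 0, 1)
            assert np.allclose(sub["duty_cycle"], expected)


class TestGenomicFixture:
    def test_all_classes_planted(self, genomic_fixture):
        counts = genomic_fixture.class_counts()
        assert set(counts) == {"tss", "intron", "loop", "none"}
        assert all(v >= 1 for v in counts.values())
        assert sum(counts.values()) == len(genomic_fixture.genes)

    def test_identifiers_unique(self, genomic_fixture):
        fx = genomic_fixture
        assert len({g.gene_id for g in fx.genes}) == len(fx.genes)
        assert len({p.peak_id for p in fx.peaks}) == len(fx.peaks)
        assert len({lp.loop_id for lp in fx.loops}) == len(fx.loops)

    def test_requires_four_genes(self):
        with pytest.raises(ValueError):
            make_genomic_fixture(3, seed=0)


class TestAbundanceFixture:
    def test_zero_noise_realises_planted_fold_change(self):
        table, truth = make_abundance_table(
            50, planted_up=5, planted_down=5, seed=2, noise_sd=0.0
        )
        a = [c for j, c in enumerate(table.columns) if j < 10]
        b = [c for j, c in enumerate(table.columns) if j >= 10]
        # loading factors scale whole columns; after equalising column sums
        # every protein's ratio equals planted x one shared constant (the
        # planted effects shift the sums), so normalise by the null ratio
        norm = table / table.sum(axis=0)
        fc = (norm[b].mean(axis=1) / norm[a].mean(axis=1)).to_numpy()
        planted = truth["planted_fold_change"].to_numpy()
        null_ratio = np.median(fc[planted == 1.0])
        assert np.allclose(fc / null_ratio, planted)

    def test_planted_counts(self, abundance_fixture):
        _, truth = abundance_fixture
        assert (truth.direction == "up").sum() == 25
        assert (truth.direction == "down").sum() == 12
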