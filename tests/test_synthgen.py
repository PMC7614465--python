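"""Schedules, behavior, activity, gene induction, and frame rendering."""

import numpy as np
import pandas as pd
import pytest

from iegflow.config import GeneratorConfig
from iegflow.errors import AnalysisError, ConfigError, DimensionError, \
    ScheduleError
from iegflow.imaging import extract_roi_fluorescence
from iegflow.synthgen import (
    build_grating_block,
    build_schedule,
    circular_masks,
    induction_kernel,
    render_frames,
    simulate_behavior,
    simulate_mouse,
)
from iegflow.synthgen.activity import draw_ground_truth, simulate_activity
from iegflow.synthgen.ieg import induction_weights, simulate_ieg
from iegflow.types import STATE_FLOW, STATE_HALT, BehaviorTrace


def _cfg(**kw):
    kw.setdefault("n_neurons_per_mouse", 30)
    kw.setdefault("fig1_segment_s", 30.0)
    kw.setdefault("fig2_segment_s", 30.0)
    kw.setdefault("n_grating_reps", 1)
    return GeneratorConfig.for_line(kw.pop("line", "Arc"), **kw)


class TestSchedule:
    def test_dark_adaptation_protocol_has_25_timepoints(self):
        sch = build_schedule("dark_adapt_fig1", _cfg())
        assert sch.n_sessions == 25
        times, _ = sch.snapshot_times_h()
        assert times.size == 25
        assert np.allclose(np.diff(sch.session_times_h), 0.25)

    def test_learning_sessions_have_seven_recordings(self):
        sch = build_schedule("learning_fig2", _cfg())
        assert sch.n_sessions == 12
        assert [s.condition_id for s in sch.sessions] == [1] * 4 + [2] * 4 + [3] * 4
        for s in sch.sessions[4:]:
            kinds = [g.kind for g in s.activity_segments]
            assert kinds == ["dark", "closed_loop", "open_loop", "open_loop",
                             "dark", "grating", "dark"]

    def test_zero_sessions_yield_empty_schedule(self):
        sch = build_schedule("learning_fig2", _cfg(), n_sessions=0)
        assert sch.n_sessions == 0

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ScheduleError):
            build_schedule("nope", _cfg())

    def test_type_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(type_fractions={"visual": 0.5, "motor": 0.2,
                                            "mismatch": 0.2, "untuned": 0.2})


class TestGratingBlock:
    def test_full_block_has_80_trials(self):
        trials = build_grating_block(8, 10)
        assert len(trials) == 80
        oris = pd.Series([t[0] for t in trials])
        assert (oris.value_counts() == 10).all()

    def test_single_trial(self):
        assert len(build_grating_block(1, 1)) == 1

    def test_seed_determinism(self):
        assert build_grating_block(8, 10, seed=5) == build_grating_block(
            8, 10, seed=5)
        assert build_grating_block(8, 10, seed=5) != build_grating_block(
            8, 10, seed=6)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ScheduleError):
            build_grating_block(0, 10)


class TestBehavior:
    def test_open_loop_replays_closed_loop_flow(self):
        cfg = _cfg()
        sch = build_schedule("learning_fig2", cfg)
        segs = simulate_behavior(sch, cfg, seed=3)
        by_sess = {}
        for sb in segs:
            by_sess.setdefault(sb.session_index, {}).setdefault(sb.kind, []).append(sb)
        for si, kinds in by_sess.items():
            if "open_loop" not in kinds:
                continue
            closed = kinds["closed_loop"][0].trace.visual_flow
            for ol in kinds["open_loop"]:
                assert np.array_equal(ol.trace.visual_flow, closed)

    def test_closed_loop_coupling_outside_halts(self):
        cfg = _cfg(closed_loop_gain=1.5)
        sch = build_schedule("learning_fig2", cfg)
        for sb in simulate_behavior(sch, cfg, seed=4):
            if sb.kind != "closed_loop":
                continue
            tr = sb.trace
            outside = tr.stimulus_state == STATE_FLOW
            assert np.allclose(tr.visual_flow[outside],
                               1.5 * tr.running_speed[outside])
            assert np.all(tr.visual_flow[tr.stimulus_state == STATE_HALT] == 0)

    def test_zero_run_probability_gives_zero_traces(self):
        cfg = _cfg(mean_rest_s=np.inf)
        sch = build_schedule("learning_fig2", cfg)
        for sb in simulate_behavior(sch, cfg, seed=1):
            assert np.all(sb.trace.running_speed == 0)
            if sb.kind == "closed_loop":
                assert np.all(sb.trace.visual_flow == 0)

    def test_halt_count_tracks_eligible_exposure(self):
        # halts are Poisson-proposed but gated on running and refractory
        cfg = _cfg(fig2_segment_s=120.0, halt_rate_hz=0.03,
                   halt_refractory_s=0.0)
        sch = build_schedule("learning_fig2", cfg, n_sessions=5)
        counts, eligible_s = [], []
        for seed in range(40):
            for sb in simulate_behavior(sch, cfg, seed=seed):
                if sb.kind != "closed_loop":
                    continue
                counts.append((sb.events["kind"] == "mismatch").sum()
                              if len(sb.events) else 0)
                eligible_s.append(
                    (sb.trace.running_speed
                     > cfg.halt_speed_threshold_cm_s).mean() * 120.0)
        expected = cfg.halt_rate_hz * np.mean(eligible_s)
        observed = np.mean(counts)
        # Poisson error of the grand mean
        tol = 4 * np.sqrt(expected / len(counts))
        assert abs(observed - expected) < max(tol, 0.3)

    def test_determinism(self):
        cfg = _cfg()
        sch = build_schedule("dark_adapt_fig1", cfg)
        a = simulate_behavior(sch, cfg, seed=9)
        b = simulate_behavior(sch, cfg, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.trace.running_speed, y.trace.running_speed)
            assert np.array_equal(x.trace.visual_flow, y.trace.visual_flow)


class TestActivity:
    def test_silent_noiseless_population_is_constant(self):
        cfg = _cfg(baseline_rate_hz=0.0, snr_activity=0.0)
        truth = draw_ground_truth(cfg, seed=0)
        truth[["visual_weight", "motor_weight", "mismatch_weight"]] = 0.0
        n = 50
        beh = BehaviorTrace(np.arange(n) * 0.1, np.zeros(n), np.zeros(n),
                            np.zeros(n, dtype=np.int8))
        noisy, clean = simulate_activity(beh, truth, cfg, seed=1)
        assert np.allclose(noisy.values, noisy.values[:, :1])
        assert np.array_equal(noisy.values, clean.values)

    def test_untuned_neurons_have_zero_gains(self):
        truth = draw_ground_truth(_cfg(n_neurons_per_mouse=200), seed=1)
        unt = truth[truth["type_label"] == "untuned"]
        assert (unt[["visual_weight", "motor_weight",
                     "mismatch_weight"]] == 0).all().all()

    def test_type_fractions_respected(self):
        truth = draw_ground_truth(_cfg(n_neurons_per_mouse=200), seed=1)
        counts = truth["type_label"].value_counts()
        assert counts["visual"] == 60 and counts["untuned"] == 50

    def test_seed_determinism(self):
        cfg = _cfg()
        truth = draw_ground_truth(cfg, seed=2)
        n = 100
        beh = BehaviorTrace(np.arange(n) * 0.1, np.zeros(n), np.zeros(n),
                            np.zeros(n, dtype=np.int8))
        a, _ = simulate_activity(beh, truth, cfg, seed=5)
        b, _ = simulate_activity(beh, truth, cfg, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_dimension_mismatch_rejected(self):
        cfg = _cfg()
        truth = draw_ground_truth(cfg, seed=2)
        n = 10
        beh = BehaviorTrace(np.arange(n) * 0.1, np.zeros(n), np.zeros(n),
                            np.zeros(n, dtype=np.int8))
        with pytest.raises(DimensionError):
            simulate_activity(beh, truth, cfg, excitability=np.ones(3))


class TestInductionKernel:
    def test_peak_at_configured_delay(self):
        cfg = _cfg()
        t = np.arange(0.0, 12.0, 0.01)
        k = induction_kernel(t, cfg)
        assert t[np.argmax(k)] == pytest.approx(cfg.induction_delay_h, abs=0.02)

    @pytest.mark.parametrize("delay", [1.0, 2.0, 3.5, 5.0])
    def test_peak_follows_delay_parameter(self, delay):
        cfg = _cfg(induction_delay_h=delay)
        t = np.arange(0.0, 15.0, 0.01)
        k = induction_kernel(t, cfg)
        assert t[np.argmax(k)] == pytest.approx(delay, abs=0.02)

    def test_causal_and_normalized(self):
        cfg = _cfg()
        t = np.arange(-5.0, 60.0, 0.01)
        k = induction_kernel(t, cfg)
        assert np.all(k[t < 0] == 0)
        assert np.trapezoid(k, t) == pytest.approx(1.0, abs=1e-3)

    def test_block_weights_sum_to_kernel_mass(self):
        cfg = _cfg()
        sess = np.arange(25) * 0.25
        W = induction_weights(np.array([6.0]), sess, cfg)
        # snapshot at 6 h sees nearly the full kernel history
        assert 0.8 < W.sum() <= 1.0


class TestSimulateIeg:
    def _inputs(self, cfg, n_sessions=25):
        truth = draw_ground_truth(cfg, seed=3)
        rng = np.random.default_rng(0)
        u = rng.lognormal(0, 1, (cfg.n_neurons_per_mouse, n_sessions))
        times = np.arange(n_sessions) * 0.25
        return truth, u, times

    def test_impulse_of_activity_peaks_at_delay(self):
        cfg = _cfg(snr_ieg=0.0, ieg_baseline_sd=0.0)
        truth, u, times = self._inputs(cfg)
        u = np.zeros_like(u)
        u[:, 2] = np.linspace(1, 2, cfg.n_neurons_per_mouse)  # impulse at 0.5 h
        snap = simulate_ieg(u, times, times, truth, cfg, seed=0)
        mean_expr = snap.values.mean(axis=0)
        peak = times[np.argmax(mean_expr)]
        assert peak == pytest.approx(0.5 + cfg.induction_delay_h, abs=0.25)

    def test_zero_coupling_gain_leaves_baseline(self):
        cfg = _cfg(coupling_gain=0.0)
        truth, u, times = self._inputs(cfg)
        snap = simulate_ieg(u, times, times, truth, cfg, seed=0)
        assert np.allclose(snap.values,
                           truth["ieg_baseline"].to_numpy()[:, None])

    def test_zero_coupling_population_correlation_near_zero(self):
        rs = []
        for seed in range(10):
            cfg = _cfg(coupling_gain=0.0, n_neurons_per_mouse=100)
            truth = draw_ground_truth(cfg, seed=seed)
            rng = np.random.default_rng(seed)
            u = rng.lognormal(0, 1, (100, 25))
            times = np.arange(25) * 0.25
            snap = simulate_ieg(u, times, times, truth, cfg, seed=seed + 50)
            for k in (0, 6, 14):
                rs.append(np.corrcoef(u[:, 5], snap.values[:, 5 + k])[0, 1])
        assert np.max(np.abs(rs)) < 3.0 / np.sqrt(100)

    def test_seed_determinism(self):
        cfg = _cfg()
        truth, u, times = self._inputs(cfg)
        a = simulate_ieg(u, times, times, truth, cfg, seed=4)
        b = simulate_ieg(u, times, times, truth, cfg, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_snapshots_outside_span_rejected(self):
        cfg = _cfg()
        truth, u, times = self._inputs(cfg)
        with pytest.raises(AnalysisError):
            simulate_ieg(u, times, np.array([100.0]), truth, cfg, seed=0)


class TestRenderRoundTrip:
    def test_noiseless_round_trip_is_exact(self, rng):
        cfg = _cfg(background_level=10.0)
        rois = circular_masks(5, (40, 40), radius=2, seed=1)
        traces = rng.random((5, 6)) * 50
        expr = rng.random(5) * 20
        red, green = render_frames(traces, expr, rois, cfg, seed=0,
                                   frame_shape=(40, 40), noise_sd=0.0)
        got = extract_roi_fluorescence(red, rois).values
        assert np.allclose(got, traces + 10.0, atol=1e-10)
        got_g = extract_roi_fluorescence(green, rois).values
        assert np.allclose(got_g, expr[:, None] + 10.0, atol=1e-10)

    def test_empty_mask_set_is_pure_background(self):
        from iegflow.imaging import ROITable

        cfg = _cfg(background_level=3.0)
        red, green = render_frames(np.empty((0, 4)), np.empty(0), ROITable([]),
                                   cfg, frame_shape=(10, 10), noise_sd=0.0)
        assert np.all(red == 3.0) and np.all(green == 3.0)

    def test_default_noise_round_trip_correlation(self, rng):
        cfg = _cfg(snr_activity=10.0)
        rois = circular_masks(8, (60, 60), radius=3, seed=2)
        traces = 50 + 20 * rng.standard_normal((8, 40)).cumsum(axis=1)
        traces -= traces.min() - 1
        red, _ = render_frames(traces, np.ones(8), rois, cfg, seed=3,
                               frame_shape=(60, 60))
        got = extract_roi_fluorescence(red, rois).values
        for i in range(8):
            assert np.corrcoef(got[i], traces[i])[0, 1] > 0.99

    def test_out_of_bounds_masks_rejected(self):
        from iegflow.errors import MaskError
        from iegflow.imaging import ROI, ROITable

        cfg = _cfg()
        rois = ROITable([ROI(0, [(50, 50)])])
        with pytest.raises(MaskError):
            render_frames(np.ones((1, 3)), np.ones(1), rois, cfg,
                          frame_shape=(10, 10))


class TestEndToEndDeterminism:
    def test_same_seed_same_mouse(self):
        cfg = _cfg()
        a = simulate_mouse(cfg, "dark_adapt_fig1", seed=42)
        b = simulate_mouse(cfg, "dark_adapt_fig1", seed=42)
        assert np.array_equal(a.ieg_raw.values, b.ieg_raw.values)
        assert np.array_equal(a.segments[3].fluor.values,
                              b.segments[3].fluor.values)
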