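"""Lagged population-vector coupling and its brute-force oracles."""

import numpy as np
import pytest

from iegflow.config import GeneratorConfig
from iegflow.coupling import (
    ActivitySummarySeries,
    bootstrap_t_compare,
    lagged_population_correlation,
    mean_vs_max_contrast,
    peak_statistics,
    summarize_activity,
    CorrelationCurve,
)
from iegflow.synthgen import simulate_cohort, simulate_mouse
from iegflow.types import (
    BehaviorTrace,
    FluorescenceMatrix,
    IEGSnapshotMatrix,
    MouseDataset,
    RecordingSegment,
)
from iegflow.synthgen.schedule import SegmentSpec, Session, SessionSchedule


def _dff_dataset(traces_per_session):
    """MouseDataset with given dff traces (list of neurons x samples)."""
    sessions = []
    segments = []
    for s, tr in enumerate(traces_per_session):
        sessions.append(Session(time_h=float(s), condition_id=1, segments=[
            SegmentSpec("dark", tr.shape[1] * 0.1),
            SegmentSpec("ieg_snapshot", 0.0),
        ]))
        n = tr.shape[1]
        beh = BehaviorTrace(np.arange(n) * 0.1, np.zeros(n), np.zeros(n),
                            np.zeros(n, dtype=np.int8))
        segments.append(RecordingSegment(
            kind="dark", session_index=s, segment_index=0, t_start_h=float(s),
            behavior=beh,
            fluor=FluorescenceMatrix(tr, np.arange(n) * 0.1, kind="dff"),
        ))
    sched = SessionSchedule("dark_adapt_fig1", sessions)
    return MouseDataset("m0", "Arc", sched, segments)


class TestSummarizeActivity:
    def test_constant_trace(self):
        ds = _dff_dataset([np.full((2, 5), 0.7)])
        out = summarize_activity(ds, mode="mean")
        assert np.allclose(out.values, 0.7)
        out = summarize_activity(ds, mode="max")
        assert np.allclose(out.values, 0.7)

    def test_mean_and_max_of_simple_trace(self):
        ds = _dff_dataset([np.array([[0.0, 1.0, 0.0]])])
        assert summarize_activity(ds, "mean").values[0, 0] == pytest.approx(1 / 3)
        assert summarize_activity(ds, "max").values[0, 0] == pytest.approx(1.0)

    def test_concatenated_equal_segments_average(self, rng):
        # mean over concatenated equal-length segments == mean of segment means
        a = rng.random((3, 10))
        b = rng.random((3, 10))
        sessions = [Session(0.0, 1, [SegmentSpec("dark", 1.0),
                                     SegmentSpec("dark", 1.0),
                                     SegmentSpec("ieg_snapshot", 0.0)])]
        segs = []
        for j, tr in enumerate((a, b)):
            n = tr.shape[1]
            beh = BehaviorTrace(np.arange(n) * 0.1, np.zeros(n), np.zeros(n),
                                np.zeros(n, dtype=np.int8))
            segs.append(RecordingSegment(
                "dark", 0, j, 0.0, beh,
                fluor=FluorescenceMatrix(tr, np.arange(n) * 0.1, kind="dff")))
        ds = MouseDataset("m", "Arc", SessionSchedule("dark_adapt_fig1",
                                                      sessions), segs)
        got = summarize_activity(ds, "mean").values[:, 0]
        assert np.allclose(got, (a.mean(1) + b.mean(1)) / 2, atol=1e-12)


def _brute_force_curve(act, ieg, lag_grid):
    """Exhaustive pair enumeration oracle."""
    tol = (lag_grid[1] - lag_grid[0]) / 2 if lag_grid.size > 1 else 0.125
    r_out = np.full(lag_grid.size, np.nan)
    for k, lag in enumerate(lag_grid):
        rs = []
        for ia, ta in enumerate(act.timepoint_h):
            for ii, ti in enumerate(ieg.timepoint_h):
                d = ti - ta
                # pair assigned to its nearest lag bin
                nearest = lag_grid[np.argmin(np.abs(lag_grid - d))]
                if nearest != lag or abs(d - lag) > tol + 1e-9:
                    continue
                a = act.values[:, ia]
                b = ieg.values[:, ii]
                if a.std() == 0 or b.std() == 0:
                    continue
                rs.append(np.corrcoef(a, b)[0, 1])
        if rs:
            r_out[k] = np.mean(rs)
    return r_out


class TestLaggedCorrelation:
    def test_identical_vectors_give_unit_correlation_at_zero_lag(self, rng):
        v = rng.random((8, 4))
        t = np.arange(4.0)
        act = ActivitySummarySeries(v, t, "mean")
        ieg = IEGSnapshotMatrix(v, t)
        curve = lagged_population_correlation(act, ieg, np.array([0.0]))
        assert np.allclose(curve.r, 1.0)

    def test_shifted_series_shifts_argmax(self, rng):
        n, T, k = 20, 12, 3
        v = rng.standard_normal((n, T))
        t = np.arange(T) * 0.25
        act = ActivitySummarySeries(v, t, "mean")
        shifted = np.roll(v, k, axis=1)
        ieg = IEGSnapshotMatrix(shifted, t)
        grid = np.arange(-4, 5) * 0.25
        curve = lagged_population_correlation(act, ieg, grid)
        assert curve.lag_h[np.nanargmax(curve.r)] == pytest.approx(k * 0.25)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_neurons = rng.integers(4, 11)
        n_tp = rng.integers(2, 6)
        act = ActivitySummarySeries(
            rng.standard_normal((n_neurons, n_tp)),
            np.sort(rng.choice(np.arange(8) * 0.25, n_tp, replace=False)),
            "mean")
        ieg = IEGSnapshotMatrix(
            rng.standard_normal((n_neurons, n_tp)),
            np.sort(rng.choice(np.arange(8) * 0.25, n_tp, replace=False)))
        grid = np.arange(-8, 9) * 0.25
        got = lagged_population_correlation(act, ieg, grid).r
        want = _brute_force_curve(act, ieg, grid)
        assert np.allclose(got, want, atol=1e-12, equal_nan=True)

    def test_role_reversal_mirrors_lags(self, rng):
        v = rng.standard_normal((10, 5))
        w = rng.standard_normal((10, 5))
        t = np.arange(5) * 0.25
        grid = np.arange(-4, 5) * 0.25
        fwd = lagged_population_correlation(
            ActivitySummarySeries(v, t, "mean"), IEGSnapshotMatrix(w, t), grid)
        rev = lagged_population_correlation(
            ActivitySummarySeries(w, t, "mean"), IEGSnapshotMatrix(v, t), grid)
        assert np.allclose(fwd.r, rev.r[::-1], atol=1e-12, equal_nan=True)

    def test_affine_invariance(self, rng):
        v = rng.random((12, 4))
        w = rng.random((12, 4))
        t = np.arange(4.0)
        grid = np.array([0.0])
        base = lagged_population_correlation(
            ActivitySummarySeries(v, t, "mean"), IEGSnapshotMatrix(w, t), grid)
        scaled = lagged_population_correlation(
            ActivitySummarySeries(2.5 * v + 1, t, "mean"),
            IEGSnapshotMatrix(0.3 * w + 7, t), grid)
        assert np.allclose(base.r, scaled.r, atol=1e-12)

    def test_lag_with_no_pairs_is_missing(self, rng):
        v = rng.random((5, 2))
        act = ActivitySummarySeries(v, np.array([0.0, 0.25]), "mean")
        ieg = IEGSnapshotMatrix(v, np.array([0.0, 0.25]))
        curve = lagged_population_correlation(act, ieg,
                                              np.arange(-8, 9) * 0.25)
        assert np.isnan(curve.r[curve.n_pairs == 0]).all()


class TestPeakStatistics:
    def test_single_peaked_curve(self):
        lag = np.arange(-2, 7) * 1.0
        r = -((lag - 3.0) ** 2)
        st = peak_statistics([CorrelationCurve(lag, r, np.ones_like(lag))])
        assert st["peak_lag_h"][0] == 3.0
        assert st["peak_r"][0] == 0.0

    def test_tie_breaks_to_earliest_lag(self):
        lag = np.array([0.0, 1.0, 2.0])
        r = np.array([0.5, 0.2, 0.5])
        st = peak_statistics([CorrelationCurve(lag, r, np.ones(3))])
        assert st["peak_lag_h"][0] == 0.0

    def test_recovers_injected_delay(self):
        cfg = GeneratorConfig.for_line("Arc", n_mice=2,
                                       n_neurons_per_mouse=150)
        from iegflow.coupling import cohort_correlation_curves

        mice = simulate_cohort(cfg, "dark_adapt_fig1", seed=3)
        st = peak_statistics(cohort_correlation_curves(mice))
        assert abs(st["peak_lag_mean"] - 3.5) <= 0.25


class TestBootstrapCompare:
    def test_self_comparison_not_significant(self):
        x = np.array([0.2, 0.3, 0.25, 0.35])
        res = bootstrap_t_compare(x, x.copy(), seed=0)
        assert res.p_value > 0.05

    def test_separated_groups_significant(self):
        a = np.array([0.0, 0.01, -0.01, 0.005])
        b = a + 10.0
        res = bootstrap_t_compare(a, b, seed=1)
        assert res.p_value < 1e-3

    def test_seed_determinism(self):
        a = np.array([0.1, 0.4, 0.3, 0.2])
        b = np.array([0.5, 0.6, 0.7, 0.55])
        r1 = bootstrap_t_compare(a, b, seed=7)
        r2 = bootstrap_t_compare(a, b, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.extra["draws_a"] == r2.extra["draws_a"]

    def test_degenerate_groups_report_p_one(self):
        res = bootstrap_t_compare([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], seed=0)
        assert res.p_value == 1.0 and res.degenerate


class TestMeanVsMaxContrast:
    @staticmethod
    def _cohort(w, seed):
        # 12-h sessions: the session's own activity carries nearly the
        # whole induction-kernel mass, as in the learning protocol
        cfg = GeneratorConfig.for_line("Arc", n_mice=2,
                                       n_neurons_per_mouse=100,
                                       fig2_segment_s=120.0,
                                       n_grating_reps=2,
                                       coupling_mode=w)
        return simulate_cohort(cfg, "learning_fig2", seed=seed, n_sessions=8)

    def test_pure_max_drive_favors_max_summary(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            out = mean_vs_max_contrast(self._cohort(1.0, seed))
            wins += out["r_max"].mean() > out["r_mean"].mean()
        assert wins >= 9

    def test_pure_mean_drive_does_not_favor_max(self):
        diffs = []
        for seed in range(10):
            out = mean_vs_max_contrast(self._cohort(0.0, seed))
            diffs.append(out["r_max"].mean() - out["r_mean"].mean())
        # no systematic ordering toward max under pure mean drive
        assert np.mean(diffs) < 0.05

    def test_single_mouse_skips_test(self):
        cfg = GeneratorConfig.for_line("Arc", n_mice=1,
                                       n_neurons_per_mouse=60,
                                       fig1_segment_s=30.0, n_grating_reps=1)
        mice = simulate_cohort(cfg, "dark_adapt_fig1", seed=2)
        out = mean_vs_max_contrast(mice)
        assert out["test"] is None
        assert np.isfinite(out["r_mean"]).all()
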