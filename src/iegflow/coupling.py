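"""Activity / IEG-expression coupling.

Per-timepoint activity summaries, the time-lagged population-vector
correlation between activity and reporter expression, peak-lag and
peak-correlation statistics across mice, the small-sample bootstrap +
t-test group comparison, and the mean-vs-max activity-summary contrast.

A population vector is the across-neuron vector of one per-neuron
statistic at one measurement timepoint.  Positive lags mean the
activity measurement preceded the expression measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import AnalysisError
from .imaging import compute_dff, normalize_ieg
from .stats import TestResult, t_test_paired, t_test_two_sample
from .types import IEGSnapshotMatrix, MouseDataset

logger = logging.getLogger(__name__)


@dataclass
class ActivitySummarySeries:
    """Per-neuron mean (or max) dF/F per measurement timepoint."""

    values: np.ndarray  # neurons x timepoints, NaN where missing
    timepoint_h: np.ndarray
    mode: str  # "mean" or "max"
    neuron_ids: Optional[np.ndarray] = None


@dataclass
class CorrelationCurve:
    """Mean pairwise population-vector correlation per lag, one mouse."""

    lag_h: np.ndarray
    r: np.ndarray  # NaN where a lag had no timepoint pairs
    n_pairs: np.ndarray
    mouse_id: str = ""


def default_lag_grid() -> np.ndarray:
    """-2 h ... +6 h in 15-min steps (the measurement cadence)."""
    return np.round(np.arange(-8, 25) * 0.25, 10)


def summarize_activity(
    dataset: MouseDataset,
    mode: str = "mean",
    segment_filter: Optional[Callable] = None,
    smooth_tau_s: Optional[float] = 0.2,
) -> ActivitySummarySeries:
    """Per neuron per session, the mean (or max) dF/F over the mapped segments.

    ``segment_filter(segment) -> bool`` restricts which activity
    segments map to each timepoint (default: all of them; use
    :func:`first_segment_filter` for the first recording of a session,
    or a kind-based filter for e.g. the grating block only).  Sessions
    with no mapped segment are marked missing (NaN).
    """
    if mode not in ("mean", "max"):
        raise AnalysisError(f"mode must be 'mean' or 'max', got {mode!r}")
    sessions = dataset.session_indices
    n = dataset.n_neurons
    values = np.full((n, len(sessions)), np.nan)
    for j, s in enumerate(sessions):
        segs = dataset.segments_of_session(s)
        if segment_filter is not None:
            segs = [g for g in segs if segment_filter(g)]
        chunks = []
        for seg in segs:
            if seg.fluor is None or seg.fluor.n_samples == 0:
                continue
            if seg.fluor.kind == "dff":
                dff = seg.fluor  # pre-extracted dF/F accepted as-is
            else:
                dff = compute_dff(seg.fluor, smooth_tau_s=smooth_tau_s)
            if dff.n_neurons != n:
                raise AnalysisError(
                    "dF/F dropped neurons; summaries would misalign"
                )
            chunks.append(dff.values)
        if not chunks:
            logger.warning("session %d of %s has no usable segments; "
                           "timepoint marked missing", s, dataset.mouse_id)
            continue
        dff_all = np.concatenate(chunks, axis=1)
        values[:, j] = dff_all.mean(axis=1) if mode == "mean" else dff_all.max(axis=1)
    times = dataset.schedule.session_times_h[np.asarray(sessions)]
    return ActivitySummarySeries(values, times, mode)


def first_segment_filter(dataset: MouseDataset) -> Callable:
    """Filter selecting only the first activity segment of each session."""
    first = {}
    for seg in dataset.segments:
        cur = first.get(seg.session_index)
        if cur is None or seg.segment_index < cur:
            first[seg.session_index] = seg.segment_index
    return lambda seg: seg.segment_index == first[seg.session_index]


def _pearson_across_neurons(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def lagged_population_correlation(
    act: ActivitySummarySeries,
    ieg: IEGSnapshotMatrix,
    lag_grid: Optional[np.ndarray] = None,
    mouse_id: str = "",
) -> CorrelationCurve:
    """Mean population-vector correlation at each lag.

    For each lag L, every (activity timepoint t_a, expression timepoint
    t_i) pair whose difference t_i - t_a falls nearest to L (within half
    a grid step) contributes the Pearson correlation across neurons
    between the two population vectors; pair correlations are averaged
    per lag with equal weight.  Lags with no pairs are NaN, not zero.
    """
    if act.values.shape[0] != ieg.values.shape[0]:
        raise AnalysisError("activity and IEG must share the neuron set")
    lag_grid = default_lag_grid() if lag_grid is None else np.asarray(lag_grid,
                                                                      dtype=float)
    if lag_grid.size > 1:
        steps = np.diff(lag_grid)
        if np.ptp(steps) > 1e-9:
            raise AnalysisError("lag grid must be uniform")
        tol = float(steps[0]) / 2.0
    else:
        tol = 0.125
    r_sum = np.zeros(lag_grid.size)
    n_pairs = np.zeros(lag_grid.size, dtype=int)
    for ia, ta in enumerate(act.timepoint_h):
        if not np.any(np.isfinite(act.values[:, ia])):
            continue
        for ii, ti in enumerate(ieg.timepoint_h):
            d = ti - ta
            k = int(np.argmin(np.abs(lag_grid - d)))
            if abs(lag_grid[k] - d) > tol + 1e-9:
                continue
            r = _pearson_across_neurons(act.values[:, ia], ieg.values[:, ii])
            if np.isfinite(r):
                r_sum[k] += r
                n_pairs[k] += 1
    with np.errstate(invalid="ignore"):
        r = np.where(n_pairs > 0, r_sum / np.maximum(n_pairs, 1), np.nan)
    return CorrelationCurve(lag_grid, r, n_pairs, mouse_id=mouse_id)


def cohort_correlation_curves(
    datasets: Sequence[MouseDataset],
    lag_grid: Optional[np.ndarray] = None,
    mode: str = "mean",
    segment_filter: Optional[Callable] = None,
) -> List[CorrelationCurve]:
    """One lagged correlation curve per mouse (normalized expression)."""
    curves = []
    for ds in datasets:
        act = summarize_activity(ds, mode=mode, segment_filter=segment_filter)
        ieg = normalize_ieg(ds.ieg_raw)
        ieg = _last_snapshot_per_session(ieg)
        curves.append(
            lagged_population_correlation(act, ieg, lag_grid,
                                          mouse_id=ds.mouse_id)
        )
    return curves


def _last_snapshot_per_session(ieg: IEGSnapshotMatrix) -> IEGSnapshotMatrix:
    """Keep the last snapshot of each session (the session's timepoint)."""
    if ieg.session_index is None:
        return ieg
    keep = []
    for s in np.unique(ieg.session_index):
        idx = np.where(ieg.session_index == s)[0]
        keep.append(idx[np.argmax(ieg.timepoint_h[idx])])
    keep = np.sort(np.array(keep))
    return IEGSnapshotMatrix(
        ieg.values[:, keep], ieg.timepoint_h[keep], normalized=ieg.normalized,
        neuron_ids=ieg.neuron_ids, session_index=ieg.session_index[keep],
    )


def peak_statistics(curves: Sequence[CorrelationCurve]) -> dict:
    """Per-mouse peak lag / peak r, and the group mean +/- SEM of each.

    Argmax ties break to the earliest lag.
    """
    peak_lag, peak_r = [], []
    for c in curves:
        ok = np.isfinite(c.r)
        if not np.any(ok):
            raise AnalysisError(f"curve {c.mouse_id!r} has no valid lag")
        rmax = np.max(c.r[ok])
        idx = np.where(ok & (c.r >= rmax))[0][0]  # earliest-lag tie-break
        peak_lag.append(float(c.lag_h[idx]))
        peak_r.append(float(c.r[idx]))
    peak_lag = np.array(peak_lag)
    peak_r = np.array(peak_r)

    def _mean_sem(x):
        m = float(x.mean())
        sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
        return m, sem

    lag_mean, lag_sem = _mean_sem(peak_lag)
    r_mean, r_sem = _mean_sem(peak_r)
    return {
        "peak_lag_h": peak_lag,
        "peak_r": peak_r,
        "peak_lag_mean": lag_mean,
        "peak_lag_sem": lag_sem,
        "peak_r_mean": r_mean,
        "peak_r_sem": r_sem,
    }


def mean_curve(curves: Sequence[CorrelationCurve]) -> CorrelationCurve:
    """Mouse-averaged correlation curve (NaN-aware)."""
    lag = curves[0].lag_h
    rs = np.stack([c.r for c in curves])
    with np.errstate(invalid="ignore"):
        r = np.nanmean(rs, axis=0)
    n = np.sum(np.stack([c.n_pairs for c in curves]), axis=0)
    return CorrelationCurve(lag, r, n, mouse_id="mean")


def bootstrap_t_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_boot: int = 5,
    seed: int = 0,
) -> TestResult:
    """Small-sample group comparison: bootstrap then t-test.

    Each group (resampling unit = mouse) is resampled with replacement
    ``n_boot`` times; the pooled resampled values are compared with a
    two-sample pooled-variance t-test.  The resample draws are logged in
    the result for reproducibility.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("each group needs >= 2 mice")
    rng = np.random.default_rng(seed)
    draws_a = rng.integers(0, a.size, size=(n_boot, a.size))
    draws_b = rng.integers(0, b.size, size=(n_boot, b.size))
    pooled_a = a[draws_a].ravel()
    pooled_b = b[draws_b].ravel()
    if pooled_a.std(ddof=1) == 0 and pooled_b.std(ddof=1) == 0:
        logger.warning("bootstrap_t_compare: degenerate zero-variance pooled "
                       "samples; reporting p = 1")
        res = TestResult(0.0, 1.0, float(pooled_a.size + pooled_b.size - 2),
                         (pooled_a.size, pooled_b.size),
                         "bootstrap_t", seed=seed, degenerate=True)
    else:
        res = t_test_two_sample(pooled_a, pooled_b, equal_var=True)
        res.method = "bootstrap_t"
        res.seed = seed
    res.extra["draws_a"] = draws_a.tolist()
    res.extra["draws_b"] = draws_b.tolist()
    return res


def mean_vs_max_contrast(
    datasets: Sequence[MouseDataset],
    smooth_tau_s: Optional[float] = 0.2,
) -> dict:
    """Session-averaged activity/expression correlation, mean vs max mode.

    Per mouse and session, the population vectors of mean (or max) dF/F
    of the first recording segment are correlated with the session's
    last expression snapshot; correlations are averaged over sessions.
    Returns per-mouse pairs and the paired t-test between modes (omitted
    for fewer than 2 mice).
    """
    r_mean, r_max = [], []
    for ds in datasets:
        filt = first_segment_filter(ds)
        ieg = _last_snapshot_per_session(normalize_ieg(ds.ieg_raw))
        per_mode = {}
        for mode in ("mean", "max"):
            act = summarize_activity(ds, mode=mode, segment_filter=filt,
                                     smooth_tau_s=smooth_tau_s)
            rs = []
            for j in range(act.timepoint_h.size):
                if j >= ieg.n_timepoints:
                    break
                r = _pearson_across_neurons(act.values[:, j], ieg.values[:, j])
                if np.isfinite(r):
                    rs.append(r)
            per_mode[mode] = float(np.mean(rs)) if rs else np.nan
        r_mean.append(per_mode["mean"])
        r_max.append(per_mode["max"])
    out = {"r_mean": np.array(r_mean), "r_max": np.array(r_max), "test": None}
    if len(datasets) >= 2:
        out["test"] = t_test_paired(out["r_max"], out["r_mean"])
    return out
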