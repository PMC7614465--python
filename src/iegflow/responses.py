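"""Event-triggered functional characterization.

Running-onset, grating-onset and visuomotor-mismatch responses
(baseline-subtracted event-triggered dF/F, z-scored over the
population), top-decile selection of high-expressing neurons, per-neuron
running / visual-flow correlations in open loop, and group contrasts.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coupling import _last_snapshot_per_session
from .errors import AnalysisError
from .imaging import compute_dff, normalize_ieg
from .stats import t_test_one_sample, t_test_two_sample
from .types import BehaviorTrace, FluorescenceMatrix, IEGSnapshotMatrix, MouseDataset

logger = logging.getLogger(__name__)

BASELINE_WINDOW_S = (-0.5, -0.1)
RESPONSE_WINDOW_S = 1.5


def detect_running_onsets(
    behavior: BehaviorTrace,
    threshold_cm_s: float = 1.0,
    quiet_s: float = 1.0,
    min_run_s: float = 1.0,
) -> pd.DataFrame:
    """Upward threshold crossings after quiescence, sustained for min_run_s.

    Returns an event table with segment-local times; zero onsets is a
    valid result.
    """
    above = behavior.running_speed > threshold_cm_s
    t = behavior.time_s
    if t.size < 2:
        return pd.DataFrame({"time_s": [], "kind": []})
    dt = float(np.median(np.diff(t)))
    n_quiet = max(int(round(quiet_s / dt)), 1)
    n_run = max(int(round(min_run_s / dt)), 1)
    onsets = []
    for i in range(1, above.size):
        if above[i] and not above[i - 1]:
            lo = i - n_quiet
            if lo < 0 or np.any(above[lo:i]):
                continue
            hi = i + n_run
            if hi > above.size or not np.all(above[i:hi]):
                continue
            onsets.append(float(t[i]))
    return pd.DataFrame({"time_s": onsets, "kind": ["running_onset"] * len(onsets)})


def event_triggered_response(
    dff: FluorescenceMatrix,
    event_times_s: Sequence[float],
    baseline_window_s: Tuple[float, float] = BASELINE_WINDOW_S,
    response_window_s: float = RESPONSE_WINDOW_S,
) -> np.ndarray:
    """Per-neuron mean baseline-subtracted event response.

    For each event, the mean dF/F over ``[0, response_window_s)`` minus
    the mean over the baseline window (default -500 ms to -100 ms before
    onset); averaged over events.  Events whose windows are truncated by
    the trace span are dropped and logged.  Returns NaN per neuron when
    no event survives.
    """
    t = dff.time_s
    values = np.zeros(dff.n_neurons)
    n_used = 0
    n_dropped = 0
    b0, b1 = baseline_window_s
    for ev in event_times_s:
        base = (t >= ev + b0) & (t < ev + b1)
        resp = (t >= ev) & (t < ev + response_window_s)
        if (not np.any(base) or not np.any(resp)
                or ev + b0 < t[0] or ev + response_window_s > t[-1] + 1e-9):
            n_dropped += 1
            continue
        values += dff.values[:, resp].mean(axis=1) - dff.values[:, base].mean(axis=1)
        n_used += 1
    if n_dropped:
        logger.info("event_triggered_response: dropped %d truncated events",
                    n_dropped)
    if n_used == 0:
        return np.full(dff.n_neurons, np.nan)
    return values / n_used


def zscore_over_population(responses: np.ndarray) -> np.ndarray:
    """(x - mean over all neurons) / SD over all neurons."""
    x = np.asarray(responses, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise AnalysisError("z-scoring needs >= 2 finite values")
    sd = x[ok].std()
    if sd == 0:
        raise AnalysisError("z-scoring needs nonzero population SD")
    return (x - x[ok].mean()) / sd


def select_high_ieg(
    ieg: IEGSnapshotMatrix,
    reference_sessions: Sequence[int],
    fraction: float = 0.10,
) -> np.ndarray:
    """Top-``fraction`` neurons by mean expression over reference snapshots.

    The selected count is round-half-up(fraction * N); ranking ties
    break deterministically toward the lower neuron id.  Returns the
    selected neuron ids.
    """
    if not 0.0 < fraction <= 1.0:
        raise AnalysisError("fraction must be in (0, 1]")
    if ieg.session_index is not None:
        cols = np.isin(ieg.session_index, np.asarray(reference_sessions))
    else:
        cols = np.isin(np.arange(ieg.n_timepoints),
                       np.asarray(reference_sessions))
    if not np.any(cols):
        raise AnalysisError("reference sessions not present in snapshot matrix")
    score = ieg.values[:, cols].mean(axis=1)
    n = score.size
    k = int(math.floor(fraction * n + 0.5))  # round half up
    ids = np.asarray(ieg.neuron_ids)
    order = np.lexsort((ids, -score))  # by -score, ties by ascending id
    return np.sort(ids[order[:k]])


def behavior_correlations(
    dataset: MouseDataset,
    smooth_tau_s: Optional[float] = 0.2,
    conditions: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per-neuron correlation with running and with visual flow in open loop.

    Each neuron's concatenated open-loop dF/F is Pearson-correlated with
    the concatenated running trace and, separately, with the visual-flow
    trace.  Constant behavior traces yield NaN (marked missing).
    """
    segs = [s for s in dataset.segments if s.kind == "open_loop"]
    if conditions is not None:
        cond = dataset.schedule.condition_ids
        segs = [s for s in segs if cond[s.session_index] in conditions]
    if not segs:
        raise AnalysisError("no open-loop segments available")
    dff_chunks, run_chunks, flow_chunks = [], [], []
    for seg in segs:
        dff = (seg.fluor if seg.fluor.kind == "dff"
               else compute_dff(seg.fluor, smooth_tau_s=smooth_tau_s))
        dff_chunks.append(dff.values)
        run_chunks.append(seg.behavior.running_speed)
        flow_chunks.append(seg.behavior.visual_flow)
    dff = np.concatenate(dff_chunks, axis=1)
    run = np.concatenate(run_chunks)
    flow = np.concatenate(flow_chunks)

    def _corr(traces: np.ndarray, b: np.ndarray) -> np.ndarray:
        if b.std() == 0:
            return np.full(traces.shape[0], np.nan)
        bc = b - b.mean()
        tc = traces - traces.mean(axis=1, keepdims=True)
        denom = np.sqrt((tc**2).sum(axis=1)) * np.sqrt((bc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, tc @ bc / denom, np.nan)

    return pd.DataFrame(
        {
            "neuron_id": np.asarray(segs[0].fluor.neuron_ids),
            "r_running": _corr(dff, run),
            "r_flow": _corr(dff, flow),
        }
    )


def group_contrast(values: np.ndarray, group_ids: Sequence[int],
                   neuron_ids: Optional[np.ndarray] = None) -> dict:
    """High-IEG group vs rest: means +/- SEM, test vs 0, between-group test."""
    values = np.asarray(values, dtype=float)
    if neuron_ids is None:
        neuron_ids = np.arange(values.size)
    in_group = np.isin(neuron_ids, np.asarray(group_ids))
    g = values[in_group & np.isfinite(values)]
    rest = values[~in_group & np.isfinite(values)]
    if g.size == 0 or rest.size == 0:
        raise AnalysisError("both groups must be non-empty")

    def _ms(x):
        return (float(x.mean()),
                float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan)

    gm, gs = _ms(g)
    rm, rs = _ms(rest)
    out = {
        "group_mean": gm, "group_sem": gs, "group_n": int(g.size),
        "rest_mean": rm, "rest_sem": rs, "rest_n": int(rest.size),
        "vs_zero": None, "vs_rest": None,
    }
    if g.size >= 2:
        if np.ptp(g) == 0 and g[0] == 0:
            logger.warning("group_contrast: all-zero group; vs-0 test skipped")
        else:
            out["vs_zero"] = t_test_one_sample(g, 0.0)
        out["vs_rest"] = t_test_two_sample(g, rest, equal_var=True)
    return out


def running_onset_zscores(
    datasets: Sequence[MouseDataset],
    conditions: Sequence[int] = (1, 2, 3),
    event_kind: str = "running_onset",
    segment_kinds: Sequence[str] = ("dark",),
    smooth_tau_s: Optional[float] = 0.2,
    detect: bool = True,
) -> np.ndarray:
    """Pooled event-triggered z-scores for one cohort (one IEG line).

    Events are detected from the running trace (or taken from the
    segment event tables for ``event_kind`` 'mismatch' /
    'grating_onset'), responses averaged over events and sessions per
    neuron, and z-scored over the pooled population of all mice.
    """
    per_mouse = []
    for ds in datasets:
        cond = ds.schedule.condition_ids
        resp = np.zeros(ds.n_neurons)
        n_ev = 0
        for seg in ds.segments:
            if cond[seg.session_index] not in conditions:
                continue
            if segment_kinds and seg.kind not in segment_kinds:
                continue
            if event_kind == "running_onset" and detect:
                ev = detect_running_onsets(seg.behavior)["time_s"].to_numpy()
            else:
                ev = seg.events[seg.events["kind"] == event_kind][
                    "time_s"].to_numpy()
            if ev.size == 0:
                continue
            dff = (seg.fluor if seg.fluor.kind == "dff"
                   else compute_dff(seg.fluor, smooth_tau_s=smooth_tau_s))
            local_ev = ev  # event tables store segment-local times
            r = event_triggered_response(
                FluorescenceMatrix(dff.values, seg.behavior.time_s, kind="dff",
                                   neuron_ids=dff.neuron_ids),
                local_ev,
            )
            if np.all(np.isfinite(r)):
                resp += r * ev.size
                n_ev += ev.size
        per_mouse.append(resp / n_ev if n_ev else np.full(ds.n_neurons, np.nan))
    pooled = np.concatenate(per_mouse)
    return zscore_over_population(pooled)


def select_high_ieg_cohort(
    datasets: Sequence[MouseDataset],
    reference_sessions: Sequence[int] = (8, 9),
    fraction: float = 0.10,
) -> np.ndarray:
    """Pooled-cohort top-decile selection (global neuron indices).

    Each mouse's expression is normalized per mouse; neurons are pooled
    across mice (offset by cumulative counts) and ranked on mean
    normalized expression over the reference sessions.
    """
    scores = []
    for ds in datasets:
        ieg = _last_snapshot_per_session(normalize_ieg(ds.ieg_raw))
        if ieg.session_index is not None:
            cols = np.isin(ieg.session_index, np.asarray(reference_sessions))
        else:
            cols = np.isin(np.arange(ieg.n_timepoints),
                           np.asarray(reference_sessions))
        if not np.any(cols):
            raise AnalysisError("reference sessions missing for "
                                f"{ds.mouse_id}")
        scores.append(ieg.values[:, cols].mean(axis=1))
    pooled = np.concatenate(scores)
    mat = IEGSnapshotMatrix(pooled[:, None], np.array([0.0]))
    return select_high_ieg(mat, [0], fraction)
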