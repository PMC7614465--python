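"""Treadmill behavior simulation.

Running is a two-state (rest/run) Markov process with exponential dwell
times; speed relaxes toward the bout target through a first-order
filter so running onsets are sharp but not instantaneous.  Closed-loop
visual flow equals ``closed_loop_gain x running_speed`` except during
inserted 1-s flow halts (the visuomotor mismatch probe); open-loop
segments replay the flow of the preceding closed-loop segment
sample-for-sample while running is generated afresh.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from ..config import GeneratorConfig
from ..errors import ScheduleError
from ..types import (
    STATE_DARK,
    STATE_FLOW,
    STATE_GRATING_DRIFTING,
    STATE_GRATING_STANDING,
    STATE_HALT,
    BehaviorTrace,
    empty_event_table,
)
from .schedule import SessionSchedule


@dataclass
class SegmentBehavior:
    session_index: int
    segment_index: int
    kind: str
    t_start_h: float
    trace: BehaviorTrace
    events: pd.DataFrame


def _simulate_running(n: int, cfg: GeneratorConfig, rng: np.random.Generator):
    """Two-state Markov running with filtered speed.

    Returns (speed, state, onset_indices); speed is exactly 0 at rest so
    onset detection has a clean quiescent baseline.
    """
    dt = 1.0 / cfg.trace_rate_hz
    p_start = min(dt / cfg.mean_rest_s, 1.0) if cfg.mean_rest_s > 0 else 1.0
    p_stop = min(dt / cfg.mean_run_bout_s, 1.0) if cfg.mean_run_bout_s > 0 else 1.0
    u = rng.random(n)
    state = np.zeros(n, dtype=bool)
    running = False
    onsets = []
    for i in range(n):
        if running:
            if u[i] < p_stop:
                running = False
        else:
            if u[i] < p_start:
                running = True
                onsets.append(i)
        state[i] = running
    # per-bout target speed, OU-filtered
    speed = np.zeros(n)
    v = 0.0
    target = 0.0
    alpha = dt / max(cfg.speed_tau_s, dt)
    noise = rng.standard_normal(n) * cfg.speed_noise * np.sqrt(dt)
    for i in range(n):
        if state[i] and (i == 0 or not state[i - 1]):
            target = cfg.run_speed_cm_s * (0.6 + 0.8 * rng.random())
        if not state[i]:
            target = 0.0
        v += alpha * (target - v)
        if state[i]:
            v += noise[i]
        else:
            v = 0.0  # hard rest: clean quiescent periods
        v = max(v, 0.0)
        speed[i] = v
    return speed, state, np.array(onsets, dtype=int)


def _insert_halts(speed: np.ndarray, flow: np.ndarray, cfg: GeneratorConfig,
                  rng: np.random.Generator):
    """Poisson-propose 1-s flow halts, gated on running and a refractory gap.

    Returns (flow_with_halts, halt_state_mask, halt_onset_indices).
    """
    n = flow.shape[0]
    dt = 1.0 / cfg.trace_rate_hz
    halt_len = max(int(round(cfg.halt_duration_s / dt)), 1)
    refr = cfg.halt_refractory_s
    mask = np.zeros(n, dtype=bool)
    onsets = []
    t = 0.0
    last_end = -np.inf
    if cfg.halt_rate_hz > 0:
        while True:
            t += rng.exponential(1.0 / cfg.halt_rate_hz)
            i = int(round(t / dt))
            if i >= n:
                break
            if t - last_end < refr:
                continue
            if speed[i] <= cfg.halt_speed_threshold_cm_s:
                continue
            j = min(i + halt_len, n)
            mask[i:j] = True
            onsets.append(i)
            last_end = t + cfg.halt_duration_s
    flow = flow.copy()
    flow[mask] = 0.0
    return flow, mask, np.array(onsets, dtype=int)


def simulate_behavior(
    schedule: SessionSchedule,
    cfg: Optional[GeneratorConfig] = None,
    seed: int = 0,
) -> List[SegmentBehavior]:
    """Simulate behavior for every activity segment of a schedule."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    dt = 1.0 / cfg.trace_rate_hz
    out: List[SegmentBehavior] = []
    for si, sess in enumerate(schedule.sessions):
        offset_s = 0.0
        last_closed_flow: Optional[np.ndarray] = None
        for gi, seg in enumerate(sess.segments):
            if seg.kind == "ieg_snapshot":
                continue
            n = int(round(seg.duration_s / dt))
            time_s = np.arange(n) * dt
            speed, _, run_onsets = _simulate_running(n, cfg, rng)
            state = np.full(n, STATE_DARK, dtype=np.int8)
            flow = np.zeros(n)
            orientation = np.full(n, np.nan)
            events = [
                {"time_s": float(time_s[i]), "kind": "running_onset",
                 "orientation": np.nan}
                for i in run_onsets
            ]
            if seg.kind == "closed_loop":
                flow = cfg.closed_loop_gain * speed
                flow, halt_mask, halt_onsets = _insert_halts(speed, flow, cfg, rng)
                state[:] = STATE_FLOW
                state[halt_mask] = STATE_HALT
                last_closed_flow = flow.copy()
                events += [
                    {"time_s": float(time_s[i]), "kind": "mismatch",
                     "orientation": np.nan}
                    for i in halt_onsets
                ]
            elif seg.kind == "open_loop":
                if last_closed_flow is None:
                    raise ScheduleError(
                        "open_loop segment without a preceding closed_loop "
                        f"segment in session {si}"
                    )
                if last_closed_flow.shape[0] >= n:
                    flow = last_closed_flow[:n].copy()
                else:  # pad a short replay with zeros
                    flow = np.zeros(n)
                    flow[: last_closed_flow.shape[0]] = last_closed_flow
                state[:] = STATE_FLOW
            elif seg.kind == "grating":
                trials = seg.grating_trials or []
                i = 0
                for ori, standing_s, drifting_s in trials:
                    n_st = int(round(standing_s / dt))
                    n_dr = int(round(drifting_s / dt))
                    state[i : i + n_st] = STATE_GRATING_STANDING
                    orientation[i : i + n_st + n_dr] = ori
                    onset = i + n_st
                    state[onset : onset + n_dr] = STATE_GRATING_DRIFTING
                    if onset < n:
                        events.append(
                            {"time_s": float(onset * dt),
                             "kind": "grating_onset", "orientation": ori}
                        )
                    i += n_st + n_dr
                    if i >= n:
                        break
            elif seg.kind != "dark":
                raise ScheduleError(f"unknown segment kind {seg.kind!r}")
            trace = BehaviorTrace(time_s, speed, flow, state, orientation)
            ev = pd.DataFrame(events) if events else empty_event_table()
            if len(ev):
                ev["session_index"] = si
                ev["segment_index"] = gi
                ev = ev.sort_values("time_s", ignore_index=True)
            out.append(
                SegmentBehavior(si, gi, seg.kind,
                                sess.time_h + offset_s / 3600.0, trace, ev)
            )
            offset_s += seg.duration_s
    return out
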