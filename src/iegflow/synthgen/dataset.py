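"""Assemble complete synthetic mouse datasets.

A mouse is a schedule, per-segment behavior + fluorescence, a raw IEG
snapshot matrix and the ground-truth table.  Per-session excitability
(a lognormal AR(1) across sessions) is the slow gain modulation that
makes population activity patterns drift over timepoints — the signal
the activity/expression coupling analysis recovers.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from ..config import GeneratorConfig
from ..types import MouseDataset, RecordingSegment
from .activity import draw_ground_truth, simulate_activity
from .behavior import simulate_behavior
from .ieg import simulate_ieg
from .schedule import SessionSchedule, build_schedule


def _excitability(cfg: GeneratorConfig, n_sessions: int,
                  rng: np.random.Generator) -> np.ndarray:
    """neurons x sessions lognormal AR(1) gain, unit mean."""
    n = cfg.n_neurons_per_mouse
    sig, rho = cfg.excitability_sd, cfg.excitability_rho
    x = np.zeros((n, n_sessions))
    if n_sessions:
        x[:, 0] = sig * rng.standard_normal(n)
        for s in range(1, n_sessions):
            x[:, s] = rho * x[:, s - 1] + sig * np.sqrt(1 - rho**2) * \
                rng.standard_normal(n)
    return np.exp(x - sig**2 / 2.0)


def _session_stats(segments: List[RecordingSegment],
                   n_neurons: int) -> np.ndarray:
    """(mean, max) of noise-free dF/F over a session's segments."""
    chunks = []
    for seg in segments:
        f = seg.fluor_clean.values
        med = np.median(f, axis=1, keepdims=True)
        med = np.where(med > 0, med, 1.0)
        chunks.append((f - med) / med)
    if not chunks:
        return np.zeros((2, n_neurons))
    dff = np.concatenate(chunks, axis=1)
    return np.stack([dff.mean(axis=1), dff.max(axis=1)])


def _mix_summaries(mean_a: np.ndarray, max_a: np.ndarray,
                   w: float) -> np.ndarray:
    """Convex mean/max mixture with components brought to a common scale.

    Mean and max dF/F live on very different numeric scales; each
    component is divided by its own population SD before mixing so the
    mixture weight w is an effective (variance-share) weight.
    """
    s_mean = mean_a.std() or 1.0
    s_max = max_a.std() or 1.0
    return (1.0 - w) * mean_a / s_mean + w * max_a / s_max


def simulate_mouse(
    cfg: GeneratorConfig,
    protocol: str = "dark_adapt_fig1",
    seed: int = 0,
    mouse_id: str = "mouse00",
    n_sessions: Optional[int] = None,
    schedule: Optional[SessionSchedule] = None,
) -> MouseDataset:
    """Simulate one mouse end to end (behavior, activity, expression)."""
    ss = np.random.SeedSequence([int(seed), 977])
    s_truth, s_beh, s_act, s_ieg, s_exc = ss.spawn(5)
    if schedule is None:
        schedule = build_schedule(
            protocol, cfg, n_sessions=n_sessions,
            seed=int(s_beh.generate_state(1)[0] % (2**31)),
        )
    truth = draw_ground_truth(cfg, seed=s_truth)
    exc = _excitability(cfg, schedule.n_sessions,
                        np.random.default_rng(s_exc))
    behaviors = simulate_behavior(schedule, cfg, seed=s_beh)

    segments: List[RecordingSegment] = []
    act_rng = np.random.default_rng(s_act)
    for sb in behaviors:
        seg_seed = int(act_rng.integers(2**31))
        noisy, clean = simulate_activity(
            sb.trace, truth, cfg, seed=seg_seed,
            excitability=exc[:, sb.session_index],
            t_offset_s=sb.t_start_h * 3600.0,
        )
        segments.append(
            RecordingSegment(
                kind=sb.kind,
                session_index=sb.session_index,
                segment_index=sb.segment_index,
                t_start_h=sb.t_start_h,
                behavior=sb.trace,
                fluor=noisy,
                events=sb.events,
                fluor_clean=clean,
            )
        )

    n_sess = schedule.n_sessions
    mean_a = np.zeros((cfg.n_neurons_per_mouse, n_sess))
    max_a = np.zeros((cfg.n_neurons_per_mouse, n_sess))
    for s in range(n_sess):
        segs = [g for g in segments if g.session_index == s]
        mean_a[:, s], max_a[:, s] = _session_stats(segs,
                                                   cfg.n_neurons_per_mouse)
    summary = _mix_summaries(mean_a, max_a, cfg.coupling_mode)
    snap_t, snap_sess = schedule.snapshot_times_h()
    ieg_raw = simulate_ieg(
        summary,
        schedule.session_times_h,
        snap_t,
        truth,
        cfg,
        seed=s_ieg,
        snapshot_session_index=snap_sess,
        condition_ids=schedule.condition_ids,
    )
    return MouseDataset(
        mouse_id=mouse_id,
        ieg_line=cfg.ieg_line,
        schedule=schedule,
        segments=segments,
        ieg_raw=ieg_raw,
        truth=truth,
        config=cfg,
    )


def simulate_cohort(
    cfg: GeneratorConfig,
    protocol: str = "dark_adapt_fig1",
    seed: int = 0,
    n_sessions: Optional[int] = None,
) -> List[MouseDataset]:
    """Simulate ``cfg.n_mice`` mice with per-mouse derived seeds."""
    mice = []
    for m in range(cfg.n_mice):
        mice.append(
            simulate_mouse(
                cfg,
                protocol=protocol,
                seed=int(np.random.SeedSequence([int(seed), m]).generate_state(1)[0]
                         % (2**31)),
                mouse_id=f"mouse{m:02d}",
                n_sessions=n_sessions,
            )
        )
    return mice
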