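"""Session schedules for the two experimental protocols.

``dark_adapt_fig1``: a dark-adapted mouse is imaged every 15 minutes;
the first (baseline) measurement is followed by a 15-minute visual
stimulation block, then measurements continue until 6 h later — 25
measurement timepoints in total.

``learning_fig2``: dark-reared mice are imaged twice per day (12 h
apart) for 6 days, 4 sessions per condition.  Condition 1 sessions are
dark-only; condition 2 and 3 sessions run the seven-segment sequence
dark → closed-loop → open-loop → open-loop → dark → grating → dark.
Every session carries IEG snapshots; the analysis uses the last
snapshot of each session as that session's expression timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..config import GeneratorConfig
from ..errors import ScheduleError

PROTOCOLS = ("dark_adapt_fig1", "learning_fig2")

ACTIVITY_KINDS = ("dark", "closed_loop", "open_loop", "grating")


@dataclass
class SegmentSpec:
    kind: str  # dark / closed_loop / open_loop / grating / ieg_snapshot
    duration_s: float
    grating_trials: Optional[List[Tuple[float, float, float]]] = None
    # trials: (orientation_deg, standing_s, drifting_s)


@dataclass
class Session:
    time_h: float
    condition_id: int
    segments: List[SegmentSpec] = field(default_factory=list)

    @property
    def activity_segments(self) -> List[SegmentSpec]:
        return [s for s in self.segments if s.kind in ACTIVITY_KINDS]


@dataclass
class SessionSchedule:
    protocol: str
    sessions: List[Session] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ScheduleError(f"unknown protocol {self.protocol!r}")
        times = [s.time_h for s in self.sessions]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ScheduleError("session times must be strictly increasing")
        for s in self.sessions:
            if self.protocol == "learning_fig2" and s.condition_id not in (1, 2, 3):
                raise ScheduleError(
                    f"condition_id must be 1-3, got {s.condition_id}"
                )
            if not any(seg.kind == "ieg_snapshot" for seg in s.segments):
                raise ScheduleError("every session needs >=1 ieg_snapshot segment")

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def session_times_h(self) -> np.ndarray:
        return np.array([s.time_h for s in self.sessions], dtype=float)

    @property
    def condition_ids(self) -> np.ndarray:
        return np.array([s.condition_id for s in self.sessions], dtype=int)

    def snapshot_times_h(self) -> Tuple[np.ndarray, np.ndarray]:
        """All IEG snapshot times (hours) and their session indices.

        Snapshots are placed at the running offset of the segment within
        the session, converted to hours.
        """
        times, sessions = [], []
        for i, sess in enumerate(self.sessions):
            offset_s = 0.0
            for seg in sess.segments:
                if seg.kind == "ieg_snapshot":
                    times.append(sess.time_h + offset_s / 3600.0)
                    sessions.append(i)
                offset_s += seg.duration_s
        return np.array(times, dtype=float), np.array(sessions, dtype=int)


def build_grating_block(
    n_orientations: int,
    n_reps: int,
    standing_s: float = 2.0,
    drifting_s: float = 3.0,
    seed: int = 0,
) -> List[Tuple[float, float, float]]:
    """Randomized drifting-grating trial list.

    Each of ``n_orientations`` evenly spaced orientations is presented
    ``n_reps`` times (standing then drifting phase per trial) in a
    seeded random order.  Returns ``n_orientations * n_reps`` trials of
    ``(orientation_deg, standing_s, drifting_s)``.
    """
    if n_orientations <= 0 or n_reps <= 0:
        raise ScheduleError("n_orientations and n_reps must be positive")
    orientations = np.arange(n_orientations) * (360.0 / n_orientations)
    trials = np.repeat(orientations, n_reps)
    rng = np.random.default_rng(seed)
    trials = trials[rng.permutation(trials.size)]
    return [(float(o), float(standing_s), float(drifting_s)) for o in trials]


def _grating_segment(cfg: GeneratorConfig, seed: int) -> SegmentSpec:
    trials = build_grating_block(
        cfg.n_grating_orientations,
        cfg.n_grating_reps,
        cfg.grating_standing_s,
        cfg.grating_drifting_s,
        seed=seed,
    )
    duration = sum(t[1] + t[2] for t in trials)
    return SegmentSpec("grating", duration, grating_trials=trials)


def build_schedule(
    protocol: str,
    cfg: Optional[GeneratorConfig] = None,
    n_sessions: Optional[int] = None,
    seed: int = 0,
) -> SessionSchedule:
    """Build the session schedule of one protocol.

    ``dark_adapt_fig1`` yields 25 sessions spaced 15 minutes apart: the
    baseline session (dark recording, snapshot, then the 15-min grating
    stimulation block) and 24 further dark sessions covering 6 h.
    ``learning_fig2`` yields ``n_sessions`` (default 12) sessions spaced
    12 h apart, 4 per condition.
    """
    cfg = cfg or GeneratorConfig()
    if protocol == "dark_adapt_fig1":
        n = 25 if n_sessions is None else int(n_sessions)
        sessions = []
        for k in range(n):
            # snapshot first so the expression timepoint sits exactly on
            # the 15-min session grid
            segs = [
                SegmentSpec("ieg_snapshot", 0.0),
                SegmentSpec("dark", cfg.fig1_segment_s),
            ]
            if k == 0:
                # visual stimulation block between the first and second
                # measurement
                segs.append(_grating_segment(cfg, seed))
            sessions.append(Session(time_h=0.25 * k, condition_id=1, segments=segs))
        return SessionSchedule(protocol, sessions)
    if protocol == "learning_fig2":
        n = 12 if n_sessions is None else int(n_sessions)
        sessions = []
        for k in range(n):
            condition = min(k // 4 + 1, 3)
            if condition == 1:
                segs = [
                    SegmentSpec("ieg_snapshot", 0.0),
                    SegmentSpec("dark", cfg.fig2_segment_s),
                    SegmentSpec("ieg_snapshot", 0.0),
                ]
            else:
                segs = [
                    SegmentSpec("ieg_snapshot", 0.0),
                    SegmentSpec("dark", cfg.fig2_segment_s),
                    SegmentSpec("closed_loop", cfg.fig2_segment_s),
                    SegmentSpec("open_loop", cfg.fig2_segment_s),
                    SegmentSpec("open_loop", cfg.fig2_segment_s),
                    SegmentSpec("dark", cfg.fig2_segment_s),
                    _grating_segment(cfg, seed + k),
                    SegmentSpec("dark", cfg.fig2_segment_s),
                    SegmentSpec("ieg_snapshot", 0.0),
                ]
            sessions.append(Session(time_h=12.0 * k, condition_id=condition,
                                    segments=segs))
        return SessionSchedule(protocol, sessions)
    raise ScheduleError(f"unknown protocol {protocol!r}")
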