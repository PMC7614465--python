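"""Core in-memory containers shared across the pipeline.

Conventions: arrays are neurons x samples (or neurons x timepoints),
0-based indices, times in seconds on the trace grid and hours on the
session grid, windows half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .errors import DimensionError

# stimulus_state codes on the trace grid
STATE_DARK = 0
STATE_FLOW = 1
STATE_HALT = 2
STATE_GRATING_STANDING = 3
STATE_GRATING_DRIFTING = 4

STATE_NAMES = {
    STATE_DARK: "dark",
    STATE_FLOW: "flow",
    STATE_HALT: "halt",
    STATE_GRATING_STANDING: "grating_standing",
    STATE_GRATING_DRIFTING: "grating_drifting",
}

EVENT_COLUMNS = ["time_s", "kind", "orientation", "session_index", "segment_index"]


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": pd.Series(dtype=float),
            "kind": pd.Series(dtype=object),
            "orientation": pd.Series(dtype=float),
            "session_index": pd.Series(dtype=int),
            "segment_index": pd.Series(dtype=int),
        }
    )


@dataclass
class FluorescenceMatrix:
    """Per-neuron fluorescence traces (``raw`` F or ``dff``)."""

    values: np.ndarray  # neurons x samples
    time_s: np.ndarray  # samples
    kind: str = "raw"
    neuron_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("values must be 2-D (neurons x samples)")
        if self.values.shape[1] != self.time_s.shape[0]:
            raise DimensionError(
                f"values has {self.values.shape[1]} samples but time_s has "
                f"{self.time_s.shape[0]}"
            )
        if self.time_s.size > 1 and not np.all(np.diff(self.time_s) > 0):
            raise DimensionError("time_s must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DimensionError("non-finite fluorescence values")
        if self.kind not in ("raw", "dff"):
            raise DimensionError(f"kind must be 'raw' or 'dff', got {self.kind!r}")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.values.shape[0])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
            if self.neuron_ids.shape[0] != self.values.shape[0]:
                raise DimensionError("neuron_ids length mismatch")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class IEGSnapshotMatrix:
    """Per-ROI reporter intensity at each measurement timepoint."""

    values: np.ndarray  # neurons x timepoints
    timepoint_h: np.ndarray  # timepoints, hours from experiment start
    normalized: bool = False
    neuron_ids: Optional[np.ndarray] = None
    session_index: Optional[np.ndarray] = None  # session of each snapshot

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timepoint_h = np.asarray(self.timepoint_h, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("values must be 2-D (neurons x timepoints)")
        if self.values.shape[1] != self.timepoint_h.shape[0]:
            raise DimensionError("values / timepoint_h length mismatch")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.values.shape[0])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
        if self.session_index is not None:
            self.session_index = np.asarray(self.session_index, dtype=int)
            if self.session_index.shape[0] != self.timepoint_h.shape[0]:
                raise DimensionError("session_index length mismatch")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class BehaviorTrace:
    """Behavior sampled on the trace grid of one recording segment."""

    time_s: np.ndarray
    running_speed: np.ndarray  # cm/s, >= 0
    visual_flow: np.ndarray  # flow units
    stimulus_state: np.ndarray  # STATE_* codes
    grating_orientation: np.ndarray = None  # degrees, NaN outside gratings

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.running_speed = np.asarray(self.running_speed, dtype=float)
        self.visual_flow = np.asarray(self.visual_flow, dtype=float)
        self.stimulus_state = np.asarray(self.stimulus_state, dtype=np.int8)
        if self.grating_orientation is None:
            self.grating_orientation = np.full(self.time_s.shape, np.nan)
        self.grating_orientation = np.asarray(self.grating_orientation, dtype=float)
        n = self.time_s.shape[0]
        for name in ("running_speed", "visual_flow", "stimulus_state",
                     "grating_orientation"):
            if getattr(self, name).shape[0] != n:
                raise DimensionError(f"{name} length mismatch with time_s")
        if np.any(self.running_speed < 0):
            raise DimensionError("running_speed must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.time_s.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "running_speed": self.running_speed,
                "visual_flow": self.visual_flow,
                "stimulus_state": self.stimulus_state,
                "grating_orientation": self.grating_orientation,
            }
        )


@dataclass
class RecordingSegment:
    """One ~minutes-long trace block with behavior and an event table."""

    kind: str  # dark / closed_loop / open_loop / grating
    session_index: int
    segment_index: int
    t_start_h: float
    behavior: BehaviorTrace
    fluor: Optional[FluorescenceMatrix] = None  # raw F
    events: pd.DataFrame = field(default_factory=empty_event_table)
    # noise-free fluorescence kept by the generator as ground truth
    fluor_clean: Optional[FluorescenceMatrix] = None


@dataclass
class MouseDataset:
    """All sessions, traces and IEG snapshots for one mouse."""

    mouse_id: str
    ieg_line: str
    schedule: object  # SessionSchedule
    segments: List[RecordingSegment] = field(default_factory=list)
    ieg_raw: Optional[IEGSnapshotMatrix] = None
    truth: Optional[pd.DataFrame] = None
    config: Optional[object] = None

    def segments_of_session(self, session_index: int) -> List[RecordingSegment]:
        return [s for s in self.segments if s.session_index == session_index]

    def segments_of_kind(self, kind: str) -> List[RecordingSegment]:
        return [s for s in self.segments if s.kind == kind]

    @property
    def session_indices(self) -> List[int]:
        return sorted({s.session_index for s in self.segments})

    @property
    def n_neurons(self) -> int:
        if self.truth is not None:
            return len(self.truth)
        if self.ieg_raw is not None:
            return self.ieg_raw.n_neurons
        return self.segments[0].fluor.n_neurons
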