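"""Deterministic on-disk persistence.

One HDF5 file per mouse (datasets written with ``track_times=False`` so
identical simulations produce byte-identical files), CSV mirrors for the
tidy analysis outputs, YAML for configs.  Times are seconds on the trace
grid and hours on the session grid.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Union

import h5py
import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .errors import MissingInputError
from .types import (
    BehaviorTrace,
    FluorescenceMatrix,
    IEGSnapshotMatrix,
    MouseDataset,
    RecordingSegment,
    empty_event_table,
)
from .synthgen.schedule import SegmentSpec, Session, SessionSchedule

_EVENT_COLS = ["time_s", "kind", "orientation", "session_index", "segment_index"]


def _write(group: h5py.Group, name: str, data) -> None:
    group.create_dataset(name, data=data, track_times=False)


def schedule_to_dict(schedule: SessionSchedule) -> dict:
    return {
        "protocol": schedule.protocol,
        "sessions": [
            {
                "time_h": s.time_h,
                "condition_id": s.condition_id,
                "segments": [
                    {
                        "kind": g.kind,
                        "duration_s": g.duration_s,
                        "grating_trials": g.grating_trials,
                    }
                    for g in s.segments
                ],
            }
            for s in schedule.sessions
        ],
    }


def schedule_from_dict(d: dict) -> SessionSchedule:
    sessions = [
        Session(
            time_h=s["time_h"],
            condition_id=s["condition_id"],
            segments=[
                SegmentSpec(
                    kind=g["kind"],
                    duration_s=g["duration_s"],
                    grating_trials=[tuple(t) for t in g["grating_trials"]]
                    if g.get("grating_trials") else None,
                )
                for g in s["segments"]
            ],
        )
        for s in d["sessions"]
    ]
    return SessionSchedule(d["protocol"], sessions)


def save_mouse(ds: MouseDataset, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["mouse_id"] = ds.mouse_id
        f.attrs["ieg_line"] = ds.ieg_line
        f.attrs["schedule"] = json.dumps(schedule_to_dict(ds.schedule),
                                         sort_keys=True)
        if ds.config is not None:
            f.attrs["config"] = json.dumps(ds.config.to_dict(), sort_keys=True)
        segs = f.create_group("segments", track_order=True)
        for i, seg in enumerate(ds.segments):
            g = segs.create_group(f"{i:03d}", track_order=True)
            g.attrs["kind"] = seg.kind
            g.attrs["session_index"] = seg.session_index
            g.attrs["segment_index"] = seg.segment_index
            g.attrs["t_start_h"] = seg.t_start_h
            _write(g, "fluor", seg.fluor.values)
            _write(g, "time_s", seg.fluor.time_s)
            _write(g, "neuron_ids", np.asarray(seg.fluor.neuron_ids))
            b = seg.behavior
            _write(g, "behavior_time_s", b.time_s)
            _write(g, "running_speed", b.running_speed)
            _write(g, "visual_flow", b.visual_flow)
            _write(g, "stimulus_state", b.stimulus_state)
            _write(g, "grating_orientation", b.grating_orientation)
            ev = seg.events if len(seg.events) else empty_event_table()
            _write(g, "event_time_s", ev["time_s"].to_numpy(dtype=float))
            _write(g, "event_kind",
                   np.array([str(k) for k in ev["kind"]], dtype="S32"))
            _write(g, "event_orientation",
                   ev["orientation"].to_numpy(dtype=float)
                   if "orientation" in ev else np.full(len(ev), np.nan))
        if ds.ieg_raw is not None:
            g = f.create_group("ieg")
            _write(g, "values", ds.ieg_raw.values)
            _write(g, "timepoint_h", ds.ieg_raw.timepoint_h)
            _write(g, "neuron_ids", np.asarray(ds.ieg_raw.neuron_ids))
            if ds.ieg_raw.session_index is not None:
                _write(g, "session_index", ds.ieg_raw.session_index)
        if ds.truth is not None:
            g = f.create_group("truth", track_order=True)
            for col in ds.truth.columns:
                data = ds.truth[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S32")
                _write(g, col, data)


def load_mouse(path: Union[str, Path]) -> MouseDataset:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"missing mouse file: {path}")
    with h5py.File(path, "r") as f:
        schedule = schedule_from_dict(json.loads(f.attrs["schedule"]))
        cfg = (GeneratorConfig.from_dict(json.loads(f.attrs["config"]))
               if "config" in f.attrs else None)
        segments: List[RecordingSegment] = []
        for key in sorted(f["segments"].keys()):
            g = f["segments"][key]
            behavior = BehaviorTrace(
                g["behavior_time_s"][()],
                g["running_speed"][()],
                g["visual_flow"][()],
                g["stimulus_state"][()],
                g["grating_orientation"][()],
            )
            fluor = FluorescenceMatrix(
                g["fluor"][()], g["time_s"][()], kind="raw",
                neuron_ids=g["neuron_ids"][()],
            )
            kinds = [k.decode() for k in g["event_kind"][()]]
            events = pd.DataFrame(
                {
                    "time_s": g["event_time_s"][()],
                    "kind": kinds,
                    "orientation": g["event_orientation"][()],
                    "session_index": int(g.attrs["session_index"]),
                    "segment_index": int(g.attrs["segment_index"]),
                }
            ) if kinds else empty_event_table()
            segments.append(
                RecordingSegment(
                    kind=g.attrs["kind"],
                    session_index=int(g.attrs["session_index"]),
                    segment_index=int(g.attrs["segment_index"]),
                    t_start_h=float(g.attrs["t_start_h"]),
                    behavior=behavior,
                    fluor=fluor,
                    events=events,
                )
            )
        ieg = None
        if "ieg" in f:
            g = f["ieg"]
            ieg = IEGSnapshotMatrix(
                g["values"][()], g["timepoint_h"][()], normalized=False,
                neuron_ids=g["neuron_ids"][()],
                session_index=g["session_index"][()]
                if "session_index" in g else None,
            )
        truth = None
        if "truth" in f:
            cols = {}
            for col in f["truth"]:
                data = f["truth"][col][()]
                if data.dtype.kind == "S":
                    data = np.array([x.decode() for x in data], dtype=object)
                cols[col] = data
            truth = pd.DataFrame(cols)
        return MouseDataset(
            mouse_id=str(f.attrs["mouse_id"]),
            ieg_line=str(f.attrs["ieg_line"]),
            schedule=schedule,
            segments=segments,
            ieg_raw=ieg,
            truth=truth,
            config=cfg,
        )


def curves_to_frame(curves) -> pd.DataFrame:
    rows = []
    for c in curves:
        for lag, r, n in zip(c.lag_h, c.r, c.n_pairs):
            rows.append({"mouse": c.mouse_id, "lag_h": float(lag),
                         "r": float(r), "n_pairs": int(n)})
    return pd.DataFrame(rows)


def write_tiff_stack(path: Union[str, Path], stack: np.ndarray) -> None:
    """Write one channel's frame stack as a multi-page TIFF (float32)."""
    import tifffile

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_tiff_stack(path: Union[str, Path]) -> np.ndarray:
    """Read a multi-page TIFF frame stack as frames x height x width."""
    import tifffile

    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"missing TIFF stack: {path}")
    stack = tifffile.imread(path)
    return stack[None] if stack.ndim == 2 else stack
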