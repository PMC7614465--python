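"""Frame stacks + ROI masks -> traces and IEG snapshot values.

Implements the two normalizations of the analysis: median-based dF/F of
the activity channel, and the per-mouse min/median normalization of
reporter expression, which maps the pooled expression matrix so its
minimum is 0 and its median 1.

Channel convention throughout the package: channel 0 = red (activity),
channel 1 = green (IEG reporter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .errors import MaskError, NormalizationError
from .types import FluorescenceMatrix, IEGSnapshotMatrix

logger = logging.getLogger(__name__)

CHANNEL_ACTIVITY = 0
CHANNEL_IEG = 1


@dataclass
class ROI:
    roi_id: int
    pixels: np.ndarray  # (k, 2) array of (row, col), 0-based
    plane: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise MaskError(f"ROI {self.roi_id}: pixels must be (k, 2)")
        if self.pixels.shape[0] == 0:
            raise MaskError(f"ROI {self.roi_id}: empty mask")


@dataclass
class ROITable:
    rois: List[ROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.roi_id for r in self.rois]
        if len(set(ids)) != len(ids):
            raise MaskError("duplicate roi_id in ROITable")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def ids(self) -> np.ndarray:
        return np.array([r.roi_id for r in self.rois])

    def validate_bounds(self, frame_shape) -> None:
        h, w = frame_shape
        for r in self.rois:
            rr, cc = r.pixels[:, 0], r.pixels[:, 1]
            if rr.min() < 0 or cc.min() < 0 or rr.max() >= h or cc.max() >= w:
                raise MaskError(
                    f"ROI {r.roi_id} has pixels outside frame {frame_shape}"
                )


def extract_roi_fluorescence(
    stack: np.ndarray,
    rois: ROITable,
    time_s: Optional[np.ndarray] = None,
) -> FluorescenceMatrix:
    """Mean pixel value in each ROI per frame.

    ``stack`` is frames x height x width.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise MaskError("stack must be frames x height x width")
    rois.validate_bounds(stack.shape[1:])
    n_frames = stack.shape[0]
    values = np.empty((len(rois), n_frames))
    for i, roi in enumerate(rois):
        values[i] = stack[:, roi.pixels[:, 0], roi.pixels[:, 1]].mean(axis=1)
    if time_s is None:
        time_s = np.arange(n_frames, dtype=float)
    return FluorescenceMatrix(values, time_s, kind="raw", neuron_ids=rois.ids)


def compute_dff(
    raw: FluorescenceMatrix,
    smooth_tau_s: Optional[float] = 0.2,
) -> FluorescenceMatrix:
    """Median-normalized dF/F with optional causal exponential smoothing.

    ``dff[i, t] = (F[i, t] - median_t F[i, .]) / median_t F[i, .]``.
    Neurons with non-positive median fluorescence are excluded and
    logged.  ``smooth_tau_s=None`` (or 0) disables the smoothing filter.
    """
    med = np.median(raw.values, axis=1)
    keep = med > 0
    if not np.all(keep):
        dropped = np.asarray(raw.neuron_ids)[~keep]
        logger.warning(
            "compute_dff: excluding %d neurons with non-positive median "
            "fluorescence: %s", dropped.size, dropped.tolist()
        )
    values = (raw.values[keep] - med[keep, None]) / med[keep, None]
    if smooth_tau_s and raw.time_s.size > 1:
        dt = float(np.median(np.diff(raw.time_s)))
        a = 1.0 - np.exp(-dt / smooth_tau_s)
        # causal EWMA initialized at the first sample
        zi = (1.0 - a) * values[:, :1]
        values, _ = lfilter([a], [1.0, -(1.0 - a)], values, axis=1, zi=zi)
    return FluorescenceMatrix(
        values, raw.time_s, kind="dff",
        neuron_ids=np.asarray(raw.neuron_ids)[keep],
    )


def measure_ieg(
    stacks: Sequence[np.ndarray],
    rois: ROITable,
    timepoint_h: Optional[np.ndarray] = None,
) -> IEGSnapshotMatrix:
    """Mean ROI pixel value of the mean projection at each timepoint.

    ``stacks`` is one green-channel stack (frames x H x W) or
    pre-computed mean projection (H x W) per snapshot timepoint.
    """
    values = []
    for stack in stacks:
        stack = np.asarray(stack)
        proj = stack.mean(axis=0) if stack.ndim == 3 else stack
        rois.validate_bounds(proj.shape)
        values.append(
            [proj[r.pixels[:, 0], r.pixels[:, 1]].mean() for r in rois]
        )
    values = np.array(values).T  # neurons x timepoints
    if timepoint_h is None:
        timepoint_h = np.arange(values.shape[1], dtype=float)
    return IEGSnapshotMatrix(values, timepoint_h, normalized=False,
                             neuron_ids=rois.ids)


def normalize_ieg(raw: IEGSnapshotMatrix) -> IEGSnapshotMatrix:
    """Per-mouse min/median normalization of reporter expression.

    All ROI measurements (over all ROIs and timepoints jointly) are
    shifted by their global minimum and scaled by the global median of
    the shifted values, so the output has minimum 0 and median 1.
    Raises :class:`NormalizationError` on a constant matrix.
    """
    v = raw.values
    vmin = v.min()
    vmed = np.median(v)
    if vmed - vmin <= 0:
        raise NormalizationError(
            "IEG matrix median equals minimum; cannot normalize"
        )
    out = (v - vmin) / (vmed - vmin)
    return IEGSnapshotMatrix(
        out, raw.timepoint_h, normalized=True,
        neuron_ids=raw.neuron_ids, session_index=raw.session_index,
    )
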