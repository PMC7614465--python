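"""Render dual-channel frame stacks from traces and ROI masks.

Red channel: each ROI's pixels carry its fluorescence trace value per
frame.  Green channel: each ROI carries its (static) reporter
expression.  Pixel noise is white Gaussian; overlapping masks sum.
Rendering uses a single imaging plane; the multi-plane piezo scheme is
carried only as metadata on the config.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from ..config import GeneratorConfig
from ..errors import DimensionError, MaskError
from ..imaging import ROI, ROITable


def circular_masks(
    n: int,
    frame_shape: Tuple[int, int],
    radius: int = 3,
    seed: int = 0,
    min_gap: int = 2,
) -> ROITable:
    """Non-overlapping circular somata placed uniformly at random."""
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    centers = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > 200 * n:
            raise MaskError(
                f"cannot place {n} non-overlapping ROIs of radius {radius} "
                f"in a {frame_shape} frame"
            )
        r = rng.integers(radius, h - radius)
        c = rng.integers(radius, w - radius)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= (2 * radius + min_gap) ** 2
               for r0, c0 in centers):
            centers.append((int(r), int(c)))
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = np.argwhere(yy**2 + xx**2 <= radius**2) - radius
    rois = [
        ROI(roi_id=i, pixels=disk + np.array(center))
        for i, center in enumerate(centers)
    ]
    return ROITable(rois)


def render_frames(
    traces: np.ndarray,
    expression: np.ndarray,
    rois: ROITable,
    cfg: Optional[GeneratorConfig] = None,
    seed: int = 0,
    frame_shape: Optional[Tuple[int, int]] = None,
    noise_sd: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render (red_stack, green_stack) from traces and expression.

    ``traces`` is neurons x frames (red channel, one value per frame);
    ``expression`` is one green value per neuron, painted into every
    frame.  ``noise_sd`` defaults to ``sd(traces) / snr_activity``.
    """
    cfg = cfg or GeneratorConfig()
    shape = tuple(frame_shape or cfg.frame_shape)
    traces = np.asarray(traces, dtype=float)
    expression = np.asarray(expression, dtype=float)
    if traces.ndim != 2:
        raise DimensionError("traces must be neurons x frames")
    if len(rois) != traces.shape[0] or expression.shape[0] != traces.shape[0]:
        raise DimensionError("rois / traces / expression count mismatch")
    rois.validate_bounds(shape)
    if np.any(traces < 0) or np.any(expression < 0):
        raise DimensionError("traces and expression must be non-negative")
    if noise_sd is None:
        noise_sd = (float(traces.std()) / cfg.snr_activity
                    if cfg.snr_activity > 0 else 0.0)
    rng = np.random.default_rng(seed)
    n_frames = traces.shape[1]
    red = np.full((n_frames,) + shape, cfg.background_level)
    green = np.full((n_frames,) + shape, cfg.background_level)
    for i, roi in enumerate(rois):
        rr, cc = roi.pixels[:, 0], roi.pixels[:, 1]
        red[:, rr, cc] += traces[i][:, None]
        green[:, rr, cc] += expression[i]
    if noise_sd > 0:
        red += rng.normal(0.0, noise_sd, red.shape)
        green += rng.normal(0.0, noise_sd, green.shape)
    return red, green
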