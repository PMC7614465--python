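"""Activity-driven reporter-gene induction.

Raw expression at a snapshot time ``t`` is a per-neuron baseline plus
the induction kernel applied to the history of per-session activity
summaries::

    raw_i(t) = B_i + gain * d_i * sum_s W(t, s) * g_cond(s) * u_i(s) + noise

``u_i(s)`` is the convex mixture ``(1-w)*mean + w*max`` of the neuron's
noise-free dF/F in session ``s``; the activity level of a session is
treated as piecewise-constant on a block centered on the session time,
and ``W(t, s)`` integrates the causal induction kernel over that block
(so the recovered peak lag is unbiased on the measurement grid).

The kernel is a gamma density parameterized by its mode
(``induction_delay_h``) and standard deviation (``induction_width_h``),
mixed with a small exponential persistence tail (time constant
``ieg_decay_h``) that begins at the mode — both components peak exactly
at the configured induction delay.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from ..config import GeneratorConfig
from ..errors import AnalysisError, DimensionError
from ..types import IEGSnapshotMatrix


def _gamma_params(mode: float, sd: float) -> Tuple[float, float]:
    """Gamma (shape, scale) with the given mode and standard deviation."""
    theta = 0.5 * (-mode + np.sqrt(mode**2 + 4.0 * sd**2))
    shape = 1.0 + mode / theta
    return shape, theta


def induction_kernel(t_h: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Causal induction kernel density evaluated at lags ``t_h`` (hours)."""
    t = np.asarray(t_h, dtype=float)
    shape, theta = _gamma_params(cfg.induction_delay_h, cfg.induction_width_h)
    rise = sps.gamma.pdf(t, a=shape, scale=theta)
    lam = cfg.persistence_frac
    tail = np.where(
        t >= cfg.induction_delay_h,
        np.exp(-(t - cfg.induction_delay_h) / cfg.ieg_decay_h) / cfg.ieg_decay_h,
        0.0,
    )
    return (1.0 - lam) * rise + lam * tail


def _kernel_cdf(t_h: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    t = np.asarray(t_h, dtype=float)
    shape, theta = _gamma_params(cfg.induction_delay_h, cfg.induction_width_h)
    rise = sps.gamma.cdf(t, a=shape, scale=theta)
    lam = cfg.persistence_frac
    tail = np.where(
        t >= cfg.induction_delay_h,
        1.0 - np.exp(-(t - cfg.induction_delay_h) / cfg.ieg_decay_h),
        0.0,
    )
    return (1.0 - lam) * rise + lam * tail


def induction_weights(
    snapshot_times_h: np.ndarray,
    session_times_h: np.ndarray,
    cfg: GeneratorConfig,
) -> np.ndarray:
    """Kernel mass each session block contributes to each snapshot.

    Session blocks are centered on the session times with edges at the
    midpoints between adjacent sessions (end blocks take the median
    spacing on each side).
    """
    s = np.asarray(session_times_h, dtype=float)
    t = np.asarray(snapshot_times_h, dtype=float)
    if s.size == 0:
        return np.zeros((t.size, 0))
    if s.size == 1:
        half = 0.125
        lo, hi = s - half, s + half
    else:
        mid = (s[:-1] + s[1:]) / 2.0
        step = float(np.median(np.diff(s)))
        lo = np.concatenate([[s[0] - step / 2.0], mid])
        hi = np.concatenate([mid, [s[-1] + step / 2.0]])
    # W[tp, s] = Kcdf(t - lo_s) - Kcdf(t - hi_s), K causal
    a = _kernel_cdf(np.maximum(t[:, None] - lo[None, :], 0.0), cfg)
    b = _kernel_cdf(np.maximum(t[:, None] - hi[None, :], 0.0), cfg)
    return a - b


def simulate_ieg(
    activity_summary: np.ndarray,
    session_times_h: np.ndarray,
    snapshot_times_h: np.ndarray,
    truth: pd.DataFrame,
    cfg: GeneratorConfig,
    seed: int = 0,
    snapshot_session_index: Optional[np.ndarray] = None,
    condition_ids: Optional[np.ndarray] = None,
) -> IEGSnapshotMatrix:
    """Simulate raw reporter expression at each snapshot time.

    ``activity_summary`` is neurons x sessions, already the configured
    mean/max mixture of noise-free dF/F per session.
    """
    u = np.asarray(activity_summary, dtype=float)
    s_times = np.asarray(session_times_h, dtype=float)
    t_times = np.asarray(snapshot_times_h, dtype=float)
    if u.ndim != 2 or u.shape[1] != s_times.shape[0]:
        raise DimensionError("activity_summary must be neurons x sessions")
    if u.shape[0] != len(truth):
        raise DimensionError("activity_summary neuron count mismatch with truth")
    if s_times.size and (t_times.min() < s_times.min() - 24.0
                         or t_times.max() > s_times.max() + 24.0):
        raise AnalysisError("snapshot times outside the simulated span")
    rng = np.random.default_rng(seed)

    W = induction_weights(t_times, s_times, cfg)  # tps x sessions
    if condition_ids is None:
        condition_ids = np.ones(s_times.shape[0], dtype=int)
    g_cond = np.array([cfg.condition_drive_gain.get(int(c), 1.0)
                       for c in condition_ids])
    d1 = truth["ieg_drive"].to_numpy()[:, None]
    d3 = truth["ieg_drive_condition3"].to_numpy()[:, None]
    pre = condition_ids < 3
    # per-neuron drive pattern may reorganize at condition-3 onset
    du = np.where(pre[None, :], d1 * u, d3 * u) * g_cond[None, :]
    drive = cfg.coupling_gain * du @ W.T  # neurons x tps

    scale = float(drive.std())
    noise_sd = scale / cfg.snr_ieg if (cfg.snr_ieg > 0 and scale > 0) else 0.0
    raw = (
        truth["ieg_baseline"].to_numpy()[:, None]
        + drive
        + noise_sd * rng.standard_normal(drive.shape)
    )
    return IEGSnapshotMatrix(
        raw,
        t_times,
        normalized=False,
        neuron_ids=truth["neuron_id"].to_numpy(),
        session_index=snapshot_session_index,
    )
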