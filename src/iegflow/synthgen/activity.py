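"""Ground-truth neuron populations and spike-to-fluorescence simulation.

Each neuron belongs to one functional type (visual, motor, mismatch,
untuned) with rate gains on the corresponding behavioral drives.  The
instantaneous rate is rectified, spikes are an inhomogeneous Poisson
process on the trace grid, and fluorescence is the spike train convolved
with a single-exponential calcium kernel plus white measurement noise.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ..config import LINE_DRIVE_WEIGHTS, GeneratorConfig
from ..errors import DimensionError
from ..types import (
    STATE_FLOW,
    STATE_GRATING_DRIFTING,
    STATE_GRATING_STANDING,
    STATE_HALT,
    BehaviorTrace,
    FluorescenceMatrix,
)

#: standing gratings drive visual neurons at this fraction of the
#: drifting-grating response
STANDING_GAIN = 0.3
#: direction-tuning concentration of the drifting-grating response
TUNING_KAPPA = 1.5


def _lognormal(rng: np.random.Generator, mean: float, sigma: float, size) -> np.ndarray:
    """Lognormal with the requested arithmetic mean."""
    return mean * np.exp(rng.standard_normal(size) * sigma - sigma**2 / 2.0)


def draw_ground_truth(cfg: GeneratorConfig, seed: int = 0) -> pd.DataFrame:
    """Draw per-neuron types, tuning weights and IEG induction parameters.

    Type counts follow ``cfg.type_fractions`` deterministically (largest
    remainder); ``ieg_drive`` carries the reporter line's functional-type
    bias: the tuning weights named in :data:`LINE_DRIVE_WEIGHTS` for the
    line multiply each neuron's induction drive.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_neurons_per_mouse
    types = list(cfg.type_fractions)
    edges = np.round(np.cumsum([cfg.type_fractions[t] for t in types]) * n).astype(int)
    labels = np.empty(n, dtype=object)
    start = 0
    for t, e in zip(types, edges):
        labels[start:e] = t
        start = e
    labels[start:] = types[-1]
    labels = labels[rng.permutation(n)]

    visual = np.where(labels == "visual",
                      _lognormal(rng, cfg.visual_rate_hz, 0.4, n), 0.0)
    motor = np.where(labels == "motor",
                     _lognormal(rng, cfg.motor_rate_hz, 0.4, n), 0.0)
    mismatch = np.where(labels == "mismatch",
                        _lognormal(rng, cfg.mismatch_rate_hz, 0.4, n), 0.0)
    baseline = _lognormal(rng, cfg.baseline_rate_hz, cfg.rate_lognorm_sd, n)
    pref = rng.uniform(0.0, 360.0, n)

    het = np.exp(rng.standard_normal(n) * cfg.drive_heterogeneity_sd
                 - cfg.drive_heterogeneity_sd**2 / 2.0)
    truth = pd.DataFrame(
        {
            "neuron_id": np.arange(n),
            "type_label": labels,
            "visual_weight": visual,
            "motor_weight": motor,
            "mismatch_weight": mismatch,
            "preferred_orientation": pref,
            "baseline_rate_hz": baseline,
            "f0": np.maximum(rng.normal(cfg.f0_mean, cfg.f0_sd, n), 1.0),
            "ieg_baseline": _lognormal(rng, cfg.ieg_baseline_mean,
                                       cfg.ieg_baseline_sd, n),
        }
    )
    truth["ieg_drive"] = het * _line_bias(truth, cfg)
    # an independent drive pattern used when the line's expression
    # pattern reorganizes at the onset of condition 3
    het2 = np.exp(rng.standard_normal(n) * max(cfg.drive_heterogeneity_sd, 0.5))
    truth["ieg_drive_condition3"] = (
        het2 * _line_bias(truth, cfg) if cfg.repattern_at_condition3
        else truth["ieg_drive"]
    )
    return truth


def _line_bias(truth: pd.DataFrame, cfg: GeneratorConfig) -> np.ndarray:
    bias = np.ones(len(truth))
    for col in LINE_DRIVE_WEIGHTS[cfg.ieg_line]:
        w = truth[col].to_numpy()
        mean_w = w[w > 0].mean() if np.any(w > 0) else 1.0
        bias = bias + cfg.line_selectivity * w / mean_w
    return bias


def _visual_drive(behavior: BehaviorTrace, pref_deg: np.ndarray,
                  cfg: GeneratorConfig) -> np.ndarray:
    """neurons x samples visual drive in [0, ~1]."""
    state = behavior.stimulus_state
    flow = behavior.visual_flow / max(cfg.run_speed_cm_s, 1e-9)
    drive = np.where(state == STATE_FLOW, flow, 0.0)[None, :] * np.ones(
        (pref_deg.shape[0], 1)
    )
    grating = (state == STATE_GRATING_DRIFTING) | (state == STATE_GRATING_STANDING)
    if np.any(grating):
        dtheta = np.deg2rad(behavior.grating_orientation[None, grating]
                            - pref_deg[:, None])
        tuning = np.exp(TUNING_KAPPA * (np.cos(dtheta) - 1.0))
        gain = np.where(state[grating] == STATE_GRATING_STANDING,
                        STANDING_GAIN, 1.0)
        drive[:, grating] = tuning * gain[None, :]
    return drive


def simulate_activity(
    behavior: BehaviorTrace,
    truth: pd.DataFrame,
    cfg: GeneratorConfig,
    seed: int = 0,
    excitability: Optional[np.ndarray] = None,
    t_offset_s: float = 0.0,
) -> Tuple[FluorescenceMatrix, FluorescenceMatrix]:
    """Simulate raw fluorescence for one segment.

    Returns ``(noisy, clean)`` raw-fluorescence matrices on the
    behavior's time grid; ``clean`` is the noise-free trace the
    generator keeps as ground truth for gene induction.
    """
    n = len(truth)
    if excitability is None:
        excitability = np.ones(n)
    excitability = np.asarray(excitability, dtype=float)
    if excitability.shape[0] != n:
        raise DimensionError("excitability length must match neuron count")
    rng = np.random.default_rng(seed)
    dt = 1.0 / cfg.trace_rate_hz

    vis = _visual_drive(behavior, truth["preferred_orientation"].to_numpy(), cfg)
    run = behavior.running_speed / max(cfg.run_speed_cm_s, 1e-9)
    halt = (behavior.stimulus_state == STATE_HALT).astype(float)

    rate = (
        truth["baseline_rate_hz"].to_numpy()[:, None]
        + truth["visual_weight"].to_numpy()[:, None] * vis
        + truth["motor_weight"].to_numpy()[:, None] * run[None, :]
        + truth["mismatch_weight"].to_numpy()[:, None] * halt[None, :]
    )
    rate = np.maximum(rate * excitability[:, None], 0.0)

    spikes = rng.poisson(rate * dt).astype(float)
    decay = np.exp(-dt / cfg.calcium_tau_s)
    calcium = lfilter([1.0], [1.0, -decay], spikes, axis=1)

    f0 = truth["f0"].to_numpy()[:, None]
    clean = f0 * (1.0 + cfg.dff_per_spike * calcium)
    noise_sd = cfg.dff_per_spike / cfg.snr_activity if cfg.snr_activity > 0 else 0.0
    noisy = clean + f0 * noise_sd * rng.standard_normal(clean.shape)

    time = behavior.time_s + t_offset_s
    ids = truth["neuron_id"].to_numpy()
    return (
        FluorescenceMatrix(noisy, time, kind="raw", neuron_ids=ids),
        FluorescenceMatrix(clean, time, kind="raw", neuron_ids=ids),
    )
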