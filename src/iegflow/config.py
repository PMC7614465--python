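"""Generator configuration.

:class:`GeneratorConfig` collects every knob of the synthetic-experiment
generator: cohort composition, session schedule geometry, the behavioral
model, the spike/fluorescence model, and the gene-induction model.  The
per-line presets (:data:`LINE_PRESETS`) encode the three reporter lines
(Arc, cFos, EGR1) with induction-coupling parameters calibrated so that
the default cohorts reproduce the qualitative ordering of coupling
strengths across lines (cFos strongest, EGR1 weakest).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Tuple

from .errors import ConfigError

IEG_LINES = ("Arc", "cFos", "EGR1")

NEURON_TYPES = ("visual", "motor", "mismatch", "untuned")


def _default_type_fractions() -> Dict[str, float]:
    return {"visual": 0.30, "motor": 0.30, "mismatch": 0.15, "untuned": 0.25}


def _default_condition_drive_gain() -> Dict[int, float]:
    return {1: 1.0, 2: 1.0, 3: 1.0}


@dataclass
class GeneratorConfig:
    """All parameters of the synthetic experiment generator.

    Times are seconds on the trace grid and hours on the session grid;
    rates in Hz; speeds in cm/s.  ``coupling_mode`` is the convex mixture
    weight *w* between mean- and max-activity drive of gene induction
    (0 = pure mean, 1 = pure max).
    """

    # cohort
    n_mice: int = 4
    n_neurons_per_mouse: int = 300
    type_fractions: Dict[str, float] = field(default_factory=_default_type_fractions)
    ieg_line: str = "Arc"
    seed: int = 0

    # gene-induction kernel (hours)
    induction_delay_h: float = 3.5
    induction_width_h: float = 0.5
    ieg_decay_h: float = 6.0
    persistence_frac: float = 0.05

    # activity -> expression coupling
    coupling_gain: float = 1.0
    coupling_mode: float = 0.5
    snr_ieg: float = 1.2
    ieg_baseline_mean: float = 1.0
    ieg_baseline_sd: float = 0.25
    drive_heterogeneity_sd: float = 0.30
    line_selectivity: float = 1.5
    condition_drive_gain: Dict[int, float] = field(
        default_factory=_default_condition_drive_gain
    )
    repattern_at_condition3: bool = False

    # spikes and fluorescence
    trace_rate_hz: float = 10.0
    snr_activity: float = 10.0
    baseline_rate_hz: float = 1.2
    rate_lognorm_sd: float = 0.5
    excitability_sd: float = 1.3
    excitability_rho: float = 0.7
    calcium_tau_s: float = 0.5
    dff_per_spike: float = 0.2
    f0_mean: float = 100.0
    f0_sd: float = 10.0

    # tuning gains (Hz at full drive)
    visual_rate_hz: float = 1.2
    motor_rate_hz: float = 1.0
    mismatch_rate_hz: float = 2.0

    # behavior
    mean_run_bout_s: float = 6.0
    mean_rest_s: float = 8.0
    run_speed_cm_s: float = 15.0
    speed_tau_s: float = 0.5
    speed_noise: float = 1.0
    closed_loop_gain: float = 1.0
    halt_rate_hz: float = 0.05
    halt_duration_s: float = 1.0
    halt_refractory_s: float = 5.0
    halt_speed_threshold_cm_s: float = 1.0

    # schedule geometry
    fig1_segment_s: float = 120.0
    fig2_segment_s: float = 480.0
    n_grating_orientations: int = 8
    n_grating_reps: int = 10
    grating_standing_s: float = 2.0
    grating_drifting_s: float = 3.0

    # frame rendering
    frame_shape: Tuple[int, int] = (400, 750)
    n_planes: int = 4
    background_level: float = 20.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.ieg_line not in IEG_LINES:
            raise ConfigError(
                f"ieg_line must be one of {IEG_LINES}, got {self.ieg_line!r}"
            )
        if set(self.type_fractions) != set(NEURON_TYPES):
            raise ConfigError(
                f"type_fractions must have keys {NEURON_TYPES}, "
                f"got {tuple(self.type_fractions)}"
            )
        total = sum(self.type_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"type_fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.type_fractions.values()):
            raise ConfigError("type_fractions must be non-negative")
        if self.trace_rate_hz <= 0:
            raise ConfigError("trace_rate_hz must be positive")
        for name in (
            "n_mice",
            "n_neurons_per_mouse",
            "induction_delay_h",
            "induction_width_h",
            "ieg_decay_h",
            "snr_ieg",
            "snr_activity",
            "baseline_rate_hz",
            "halt_rate_hz",
            "halt_duration_s",
            "mean_run_bout_s",
            "mean_rest_s",
            "fig1_segment_s",
            "fig2_segment_s",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.coupling_mode <= 1.0:
            raise ConfigError("coupling_mode must be in [0, 1]")
        if not 0.0 <= self.persistence_frac < 1.0:
            raise ConfigError("persistence_frac must be in [0, 1)")

    def replace(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def for_line(cls, ieg_line: str, **overrides) -> "GeneratorConfig":
        """Config preset for one reporter line (Arc / cFos / EGR1)."""
        if ieg_line not in LINE_PRESETS:
            raise ConfigError(f"unknown IEG line {ieg_line!r}")
        params = dict(LINE_PRESETS[ieg_line])
        params.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(params) - known
        if unknown:
            raise ConfigError(f"unknown GeneratorConfig fields: {sorted(unknown)}")
        return cls(ieg_line=ieg_line, **params)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_shape"] = list(self.frame_shape)
        d["condition_drive_gain"] = {
            str(k): v for k, v in self.condition_drive_gain.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown GeneratorConfig fields: {sorted(unknown)}")
        if "frame_shape" in d:
            d["frame_shape"] = tuple(d["frame_shape"])
        if "condition_drive_gain" in d:
            d["condition_drive_gain"] = {
                int(k): float(v) for k, v in d["condition_drive_gain"].items()
            }
        return cls(**d)


# Per-line presets.  ``snr_ieg`` values were calibrated against a
# brute-force simulation so the default fig-1 cohorts recover peak
# population-vector correlations ordered cFos > Arc > EGR1; the
# ``line_drive`` key names the tuning weight that multiplies each
# neuron's induction drive (the functional-type bias of the line), and
# ``condition_drive_gain`` encodes the learning-related change of drive
# at the onset of each condition.
LINE_PRESETS: Dict[str, dict] = {
    "Arc": {
        "snr_ieg": 2.2,
        "line_selectivity": 0.8,
        "induction_width_h": 0.5,
        "condition_drive_gain": {1: 1.0, 2: 1.0, 3: 2.2},
    },
    "cFos": {
        "snr_ieg": 3.0,
        "induction_width_h": 0.5,
        "condition_drive_gain": {1: 1.0, 2: 1.0, 3: 1.0},
    },
    "EGR1": {
        "snr_ieg": 0.7,
        "induction_width_h": 1.5,
        "condition_drive_gain": {1: 1.0, 2: 1.0, 3: 0.55},
    },
}

#: Which ground-truth tuning weights bias each line's induction drive.
LINE_DRIVE_WEIGHTS: Dict[str, Tuple[str, ...]] = {
    "Arc": ("visual_weight",),
    "cFos": (),
    "EGR1": ("motor_weight", "mismatch_weight"),
}
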