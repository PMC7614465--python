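import numpy as np
import pytest

from iegflow.config import GeneratorConfig
from iegflow.synthgen import simulate_cohort, simulate_mouse


@pytest.fixture(scope="session")
def small_fig1_mouse():
    """One small dark-adaptation mouse shared by read-only tests."""
    cfg = GeneratorConfig.for_line("Arc", n_neurons_per_mouse=60,
                                   fig1_segment_s=60.0, n_grating_reps=2)
    return simulate_mouse(cfg, "dark_adapt_fig1", seed=7)


@pytest.fixture(scope="session")
def small_fig2_cohort():
    """Two small visuomotor-learning mice shared by read-only tests."""
    cfg = GeneratorConfig.for_line("Arc", n_mice=2, n_neurons_per_mouse=60,
                                   fig2_segment_s=60.0, n_grating_reps=2)
    return simulate_cohort(cfg, "learning_fig2", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
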