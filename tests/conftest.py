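import numpy as np
import pytest

from quadgait.coordination import phase_series_from_footfalls
from quadgait.synthetic import SimulationConfig, simulate_footfalls


@pytest.fixture(scope="session")
def control_dataset():
    """Default control condition, ~84 hindlimb steps per condition pool."""
    cfg = SimulationConfig(seed=11, n_animals=6, passes_per_animal=3,
                           steps_per_pass=14)
    return simulate_footfalls(cfg)


@pytest.fixture(scope="session")
def silenced_dataset():
    cfg = SimulationConfig(seed=12, condition="silenced", n_animals=6,
                           passes_per_animal=3, steps_per_pass=14)
    return simulate_footfalls(cfg)


@pytest.fixture(scope="session")
def control_phases(control_dataset):
    return phase_series_from_footfalls(control_dataset.footfalls)


@pytest.fixture(scope="session")
def silenced_phases(silenced_dataset):
    return phase_series_from_footfalls(silenced_dataset.footfalls)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
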