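import numpy as np
import pytest
from hypothesis import settings

from tacrodose import SimulationConfig, TherapeuticWindow, VariabilityModel

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def window():
    return TherapeuticWindow()


@pytest.fixture(scope="session")
def small_config():
    """A fast scenario: fewer replicates, coarse weight scan."""
    return SimulationConfig(n_replicates=200, seed=42, weight_scan_step=2.0)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def no_variability():
    return VariabilityModel(0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def moderate_variability():
    return VariabilityModel(0.35, 0.30, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240131)
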