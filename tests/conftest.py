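import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from helmkit import TimeGrid, make_irf
from helmkit.presets import get_preset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return TimeGrid()


@pytest.fixture(scope="session")
def irf80(grid):
    return make_irf(80.0, grid)


@pytest.fixture(scope="session")
def irf_delta(grid):
    return make_irf(0.0, grid)


@pytest.fixture(scope="session")
def papt267():
    return get_preset("pApT", 267, "standard")


@pytest.fixture(scope="session")
def papt285():
    return get_preset("pApT", 285, "standard")


@pytest.fixture(scope="session")
def a20t20():
    return get_preset("A20T20", 285, "standard")


@pytest.fixture(scope="session")
def papt285_diluted():
    return get_preset("pApT", 285, "diluted_6x")


@pytest.fixture(scope="session")
def wide_wavelengths():
    """Wavelength grid covering the full emission band for width measurements."""
    return np.arange(280.0, 501.0, 2.0)
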