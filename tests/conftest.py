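import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eegstates import default_layout, grid_layout

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def small_layout():
    """16-channel dense grid for simulations where topology is irrelevant."""
    return grid_layout(4, 4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
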