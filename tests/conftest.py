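import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    settings(
        max_examples=25,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("suite")

from cryptdrift import CryptGeometry, KineticParams, preset


@pytest.fixture(scope="session")
def geom():
    return CryptGeometry()


@pytest.fixture(scope="session")
def si():
    return preset("SI")


@pytest.fixture(scope="session")
def li():
    return preset("LI")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
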