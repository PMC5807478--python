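import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from brainshift import table_card

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phve_card():
    return table_card("PHVE")


@pytest.fixture(scope="session")
def phe_card():
    return table_card("PHE")


@pytest.fixture(scope="session")
def hve_card():
    return table_card("HVE")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
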