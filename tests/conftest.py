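import numpy as np
import pytest
from hypothesis import settings

from snedds_screen.fixtures import reference_responses

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def celecoxib_responses():
    return reference_responses("celecoxib")


@pytest.fixture(scope="session")
def fenofibrate_responses():
    return reference_responses("fenofibrate")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
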