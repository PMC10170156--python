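import numpy as np
import pytest
from hypothesis import settings

import nanodomain as nd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def defaults() -> nd.SimParams:
    return nd.default_params()


@pytest.fixture(scope="session")
def fast_params() -> nd.SimParams:
    """Coarse short-horizon parameter set for cheap engine tests."""
    return nd.default_params(T_max=20.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
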