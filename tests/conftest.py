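import numpy as np
import pytest

from caixsim import ModelParameters, fitted_parameters


@pytest.fixture(scope="session")
def printed_params() -> ModelParameters:
    """Published parameter set as printed (phi = 2417.2 / day)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def fitted_params() -> ModelParameters:
    """Published set with the recalibrated growth rate (cached per session)."""
    return fitted_parameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
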