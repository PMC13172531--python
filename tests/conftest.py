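import numpy as np
import pytest

from oe_asym.division_mixture import MixtureParams
from oe_asym.regen_ode import DEFAULT_PARAMS


@pytest.fixture(scope="session")
def fitted_mixture_params() -> MixtureParams:
    """Mixture parameters estimated from the telophase Pol II ratio data."""
    return MixtureParams(p_s=0.45, p_b=0.23, sigma=0.09)


@pytest.fixture(scope="session")
def regen_params():
    """Rate/feedback constants estimated from the EdU time course."""
    return DEFAULT_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
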