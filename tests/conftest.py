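import numpy as np
import pytest
from hypothesis import settings

from synca.params import PlasticityParams, preset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def in_vitro():
    return preset("in_vitro")


@pytest.fixture(scope="session")
def in_vivo():
    return preset("in_vivo")


@pytest.fixture(scope="session")
def equal_amp_params():
    """Equal-amplitude variant used by the closed-form stationary solution."""
    return PlasticityParams(C_pre=1.0, C_post=1.0, tau_Ca=22.6936, D=4.6098,
                            theta_d=1.0, theta_p=1.3, gamma_d=331.909,
                            gamma_p=725.085, sigma=3.3501, tau_rho=346.3615)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
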