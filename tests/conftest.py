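import numpy as np
import pytest

from dustl import load_dataset, fit_mle


@pytest.fixture(scope="session")
def tfp():
    return load_dataset("tfp_africa")


@pytest.fixture(scope="session")
def pwid():
    return load_dataset("pwid_mortality")


@pytest.fixture(scope="session")
def tfp_mle(tfp):
    return fit_mle(tfp.sample)


@pytest.fixture(scope="session")
def pwid_mle(pwid):
    return fit_mle(pwid.sample)


@pytest.fixture(scope="session")
def param_grid():
    """Small (nu, rho) grid spanning nu < 1, nu = 1 and nu > 1."""
    return [(0.5, 1.0), (1.0, 0.5), (1.75, 2.75), (2.75, 1.5), (2.5, 1.25)]


@pytest.fixture
def rng():
    return np.random.default_rng(20240973)
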