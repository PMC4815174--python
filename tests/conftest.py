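import numpy as np
import pytest

from rtnoise import ExGaussParams, exgauss_rvs


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def fig1_params():
    """The worked-example parameter set: mu=500, sigma=50, tau=100 ms."""
    return ExGaussParams(500.0, 50.0, 100.0)


@pytest.fixture
def rt_sample(fig1_params, rng):
    """A medium ex-Gaussian RT sample for fitting tests."""
    return exgauss_rvs(fig1_params, 2000, rng)
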