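import numpy as np
import pytest

from tempgen import DDMParams, make_design, simulate_trials


@pytest.fixture(scope="session")
def exp1_design():
    return make_design("exp1")


@pytest.fixture(scope="session")
def exp1_x3_design():
    return make_design("exp1_x3")


@pytest.fixture(scope="session")
def balanced_design():
    return make_design("balanced")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ddm_trials(exp1_design):
    """A reference simulated dataset from a mid-range ddm observer."""
    return simulate_trials("ddm", DDMParams(0.3, 0.5, 0.2), exp1_design, seed=7)
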