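import numpy as np
import pytest

import lacshift as ls
from lacshift.simulate import FAST


@pytest.fixture(scope="session")
def params_A():
    return ls.load_packaged_parameters("shaken_A")


@pytest.fixture(scope="session")
def params_A_se():
    return ls.load_packaged_parameters("shaken_A", with_errors=True)[1]


@pytest.fixture(scope="session")
def params_C():
    return ls.load_packaged_parameters("stirred_C")


@pytest.fixture(scope="session")
def design_A():
    return ls.load_packaged_design("A")


@pytest.fixture(scope="session")
def design_B():
    return ls.load_packaged_design("B")


@pytest.fixture(scope="session")
def design_C():
    return ls.load_packaged_design("C")


@pytest.fixture(scope="session")
def traj_A(params_A, design_A):
    """Reference trajectory of design A at default (tight) tolerances."""
    return ls.simulate(params_A, design_A)


@pytest.fixture(scope="session")
def noisefree_A(params_A, design_A):
    """Noise-free daily-sampled synthetic experiment A (all 9 components)."""
    return ls.generate_experiment(params_A, design_A,
                                  noise=ls.NoiseModel(cv=0.0, seed=0))


@pytest.fixture(scope="session")
def noisefree_B(params_A, design_B):
    """Noise-free daily samples of the 7-day shaken design (params from A)."""
    return ls.generate_experiment(params_A, design_B,
                                  noise=ls.NoiseModel(cv=0.0, seed=0))


@pytest.fixture(scope="session")
def fast_solver():
    return FAST
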