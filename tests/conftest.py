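import numpy as np
import pytest

import odemcmc as om


@pytest.fixture(scope="session")
def m3_problem():
    return om.make_benchmark("M3")


@pytest.fixture(scope="session")
def m3_data(m3_problem):
    return om.generate_data(m3_problem, seed=1)


@pytest.fixture(scope="session")
def m3_target(m3_problem, m3_data):
    return om.PosteriorTarget(m3_problem, m3_data)


@pytest.fixture(scope="session")
def m1b_problem():
    return om.make_benchmark("M1b")


@pytest.fixture(scope="session")
def m1b_data(m1b_problem):
    return om.generate_data(m1b_problem, seed=3)


@pytest.fixture(scope="session")
def gauss2d():
    """Correlated 2-d Gaussian reference target (rho = 0.9)."""
    cov = np.array([[1.0, 0.9], [0.9, 1.0]])
    return om.GaussianTarget(mean=np.zeros(2), cov=cov)


@pytest.fixture(scope="session")
def two_state():
    return om.TwoStateTarget()
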