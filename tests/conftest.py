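import numpy as np
import pytest

import sispersist as sp


@pytest.fixture(scope="session")
def fig1_model():
    """Two groups, heterogeneous infectivity lambda = (2/51)(50, 1), R0 = 1.5."""
    return sp.validate_model([0.5, 0.5], [100 / 51, 2 / 51], [1.0, 1.0],
                             beta=1.5, gamma=1.0)


@pytest.fixture(scope="session")
def fig3_model():
    """Two groups, heterogeneous infectivity lambda = (5/3, 1/3), R0 = 1.2."""
    return sp.validate_model([0.5, 0.5], [5 / 3, 1 / 3], [1.0, 1.0],
                             beta=1.2, gamma=1.0)


@pytest.fixture(scope="session")
def homogeneous_15():
    return sp.validate_model([1.0], [1.0], [1.0], beta=1.5, gamma=1.0)


@pytest.fixture(scope="session")
def both_het_model():
    """k=2 with heterogeneity in both infectivity and susceptibility, R0=1.2."""
    lam, mu = np.array([1.3, 0.7]), np.array([1.4, 0.6])
    f = np.array([0.5, 0.5])
    beta = 1.2 / float(np.sum(f * lam * mu))
    return sp.validate_model(f, lam, mu, beta=beta, gamma=1.0, normalise=True)
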