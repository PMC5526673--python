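import numpy as np
import pytest

import quorumsim as q


@pytest.fixture(scope="session")
def sinusoidal():
    """The monostable up-regulating response R(x) = x + 0.2 sin(pi x)."""
    return q.SinusoidalResponse(0.2)


@pytest.fixture(scope="session")
def uniform_init():
    return q.InitialDistribution("uniform")


@pytest.fixture(scope="session")
def two_type_init():
    """Half non-producers (p=0), half full producers (p=1)."""
    return q.InitialDistribution("atoms", atoms={0.0: 0.5, 1.0: 0.5})


@pytest.fixture(scope="session")
def het_solution(sinusoidal):
    """Closed-form bimodal stationary state at s=0.2, lam=0.05, kappa=0.2."""
    return q.heterogeneous_solution(sinusoidal, 0.2, 0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
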