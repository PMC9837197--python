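import numpy as np
import pytest

from fcsimpute import NIWPrior, SIM_MU, SIM_SIGMA


@pytest.fixture(scope="session")
def sim_prior() -> NIWPrior:
    """The weakly-informative joint prior used throughout the experiments."""
    return NIWPrior(mu0=np.zeros(3), tau=1.0, m=3.0, Lambda=60.0 * np.eye(3))


@pytest.fixture(scope="session")
def sim_mu():
    return SIM_MU.copy()


@pytest.fixture(scope="session")
def sim_sigma():
    return SIM_SIGMA.copy()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_spd(rng: np.random.Generator, p: int, scale: float = 1.0) -> np.ndarray:
    """A well-conditioned random symmetric positive-definite matrix."""
    a = rng.standard_normal((p, p))
    return scale * (a @ a.T + p * np.eye(p))


@pytest.fixture()
def spd_factory(rng):
    return lambda p, scale=1.0: random_spd(rng, p, scale)
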