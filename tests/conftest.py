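import numpy as np
import pytest

from aamatrix import (
    Alignment,
    RateMatrix,
    builtin_matrix,
    discrete_gamma,
)


@pytest.fixture(scope="session")
def lg():
    return builtin_matrix("lg")


@pytest.fixture(scope="session")
def jtt():
    return builtin_matrix("jtt")


@pytest.fixture(scope="session")
def lg_model(lg):
    return RateMatrix.from_matrix_file(lg)


@pytest.fixture
def uniform_model():
    R = np.ones((20, 20))
    np.fill_diagonal(R, 0.0)
    return RateMatrix(R, np.full(20, 0.05))


@pytest.fixture
def gamma4():
    return discrete_gamma(0.8, 4)


def random_reversible_model(rng, normalize=True, concentration=5.0):
    """A random exchangeability matrix and frequency vector."""
    R = np.exp(rng.normal(scale=0.7, size=(20, 20)))
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 0.0)
    pi = rng.dirichlet(np.full(20, concentration))
    return RateMatrix(R, pi, normalize=normalize)


@pytest.fixture
def random_model():
    return random_reversible_model(np.random.default_rng(42))


def random_alignment(rng, taxa, s):
    from aamatrix import AMINO_ACIDS

    rows = ["".join(rng.choice(list(AMINO_ACIDS), size=s)) for _ in taxa]
    return Alignment("rand", list(taxa), rows)
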