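import numpy as np
import pytest

import mstrain as ms


@pytest.fixture(scope="session")
def case1_baseline():
    return ms.case1(model="baseline").params


@pytest.fixture(scope="session")
def case1_extended():
    return ms.case1(model="extended").params


@pytest.fixture(scope="session")
def case1_frequencies():
    v = np.array([27.0, 9.0, 3.0, 1.0])
    return v / v.sum()


def random_stochastic_matrix(rng, n, low=0.05):
    """Dense random column-stochastic matrix with positive diagonal."""
    M = rng.uniform(low, 1.0, size=(n, n))
    return M / M.sum(axis=0)


def random_extended_params(rng, n=None):
    """Admissible random extended parameter set for oracle cross-checks."""
    if n is None:
        n = int(rng.choice([1, 2, 4, 8]))
    if n == 1:
        A = ms.MutationMatrix(np.ones((1, 1)))
    else:
        A = ms.MutationMatrix(random_stochastic_matrix(rng, n))
    return ms.ExtendedParams(
        beta_C=rng.uniform(0.05, 0.5, n), xi=rng.uniform(1.0, 6.0),
        gamma=rng.uniform(1.0, 4.0), mu=rng.uniform(0.01, 0.1),
        u_T=rng.uniform(0.0, 1.0), u_P=rng.uniform(0.0, 1.0),
        zeta=rng.uniform(0.0, 0.5, n), psi=rng.uniform(0.0, 1.0, n),
        delta=rng.uniform(0.0, 5.0), A=A,
    )
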