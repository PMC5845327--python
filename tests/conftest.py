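"""Shared fixtures: simulated datasets and fitted models.

The expensive objects (EM fits on 1e5-2e5 rows) are session-scoped and
shared across test modules; everything is generated programmatically
from fixed seeds.
"""

import numpy as np
import pytest

import hteqtl as ht


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def simulate_pair_mixture(p, delta, sigma, N, seed):
    """Draw (N, 2) rows from the two-tissue mixture (independent of the
    package's simulator: explicit per-component Cholesky sampling)."""
    rng = np.random.default_rng(seed)
    s11, s12, s22 = sigma[0][0], sigma[0][1], sigma[1][1]
    covs = [
        np.array([[1, delta], [delta, 1]]),
        np.array([[1, delta], [delta, 1 + s22]]),
        np.array([[1 + s11, delta], [delta, 1]]),
        np.array([[1 + s11, delta + s12], [delta + s12, 1 + s22]]),
    ]
    idx = rng.choice(4, size=N, p=p)
    z = np.empty((N, 2))
    for g, C in enumerate(covs):
        m = idx == g
        L = np.linalg.cholesky(C)
        z[m] = rng.standard_normal((int(m.sum()), 2)) @ L.T
    return z, idx


@pytest.fixture(scope="session")
def pair_recovery():
    """Two-tissue data from known parameters plus its EM fit (N = 2e5)."""
    truth = {
        "p": np.array([0.90, 0.02, 0.02, 0.06]),
        "delta": 0.2,
        "sigma": np.array([[4.0, 3.0], [3.0, 4.0]]),
    }
    z, idx = simulate_pair_mixture(truth["p"], truth["delta"],
                                   truth["sigma"].tolist(), 200_000,
                                   seed=7)
    fit = ht.em_fit_pair(z)
    return {"truth": truth, "z": z, "idx": idx, "fit": fit}


@pytest.fixture(scope="session")
def k9_model():
    return ht.synthetic_model()


@pytest.fixture(scope="session")
def k9_sim(k9_model):
    return ht.simulate_dataset(k9_model, 100_000, seed=1)


@pytest.fixture(scope="session")
def k9_est(k9_sim):
    """HTEQTL fit to one synthetic 9-tissue replicate (36 pairwise EMs)."""
    _, zmat = k9_sim
    return ht.HTEQTL().fit(zmat)


@pytest.fixture(scope="session")
def k4_model():
    return ht.synthetic_model(K=4)


@pytest.fixture(scope="session")
def k4_sim(k4_model):
    return ht.simulate_dataset(k4_model, 100_000, seed=11)


@pytest.fixture(scope="session")
def k4_est(k4_sim):
    _, zmat = k4_sim
    return ht.HTEQTL().fit(zmat)
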