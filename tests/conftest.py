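"""Shared fixtures: small synthetic worlds, toy grids and an independent
dense GP oracle used to cross-check the package's linear algebra."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import chemoscape as cs

SQRT5 = np.sqrt(5.0)


def dense_gp_oracle(X, y, Xs, lengthscales, signal_var, noise_var, mean, nu=2.5,
                    jitter=1e-6):
    """Closed-form GP predictions via explicit matrix inversion.

    Deliberately a different code path from the package: cdist on
    pre-scaled coordinates plus numpy.linalg.inv, no Cholesky reuse.
    Returns (mean, total variance) at Xs.
    """
    ell = np.asarray(lengthscales, float)
    X = np.asarray(X, float) / ell
    Xs = np.asarray(Xs, float) / ell
    def k(r):
        if nu == 2.5:
            return signal_var * (1 + SQRT5 * r + 5 * r**2 / 3) * np.exp(-SQRT5 * r)
        if nu == 1.5:
            s3 = np.sqrt(3.0)
            return signal_var * (1 + s3 * r) * np.exp(-s3 * r)
        return signal_var * np.exp(-r)
    K = k(cdist(X, X)) + (noise_var + jitter) * np.eye(len(X))
    Kinv = np.linalg.inv(K)
    ks = k(cdist(Xs, X))
    mu = mean + ks @ Kinv @ (np.asarray(y, float) - mean)
    var = signal_var + noise_var - np.einsum("ij,jk,ik->i", ks, Kinv, ks)
    return mu, var


@pytest.fixture(scope="session")
def small_grid():
    """30 x 30 cells at 0.2 degrees, fully active."""
    return cs.build_study_grid((0.0, 5.8, 40.0, 45.8), 0.2)


@pytest.fixture(scope="session")
def tiny_panel():
    panel = cs.default_panel()
    return panel.subset(["d18O", "d2H", "Sr", "Rb"])


@pytest.fixture(scope="session")
def small_world(small_grid, tiny_panel):
    """4-variable Matérn world on the 30x30 grid (ell 2 deg, noise sd 0.25)."""
    return cs.simulate_fields(
        small_grid, tiny_panel, lengthscales=2.0, signal_var=1.0,
        noise_sd=0.25, nu=2.5, seed=11,
    )


@pytest.fixture(scope="session")
def oracle(small_world):
    return cs.OracleEnsemble(small_world)


@pytest.fixture(scope="session")
def territories(small_grid):
    return cs.synthetic_territories(small_grid, 4, seed=3)


@pytest.fixture(scope="session")
def clustered_samples(small_world):
    """Clustered field-protocol sampling from the small world (30 trees)."""
    return cs.sample_reference(small_world, n_clusters=10, seed=7)
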