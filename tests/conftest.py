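import numpy as np
import pytest

from parapatry import (DesignMatrix, GradientConfig, JsdmPosterior,
                       JsdmTrueParams, ModelSpec, generate_occurrences,
                       generate_sites)


@pytest.fixture(scope="session")
def small_sites():
    """300 synthetic survey plots along the elevation gradient."""
    return generate_sites(GradientConfig(n_sites=300, seed=11))


@pytest.fixture(scope="session")
def two_species_spec():
    return ModelSpec("base", ["elevation", "rainfall"], ["sp_a", "sp_b"])


@pytest.fixture(scope="session")
def small_occ(small_sites, two_species_spec):
    beta = np.array([[0.2, 1.0, -0.4], [-0.2, -0.9, 0.3]])
    rho = np.array([[1.0, -0.4], [-0.4, 1.0]])
    return generate_occurrences(small_sites, two_species_spec,
                                JsdmTrueParams(beta, rho), seed=5)


def make_posterior(beta_draws, rho_draws, chain=None, n_sites=10, seed=0):
    """Hand-built posterior around a random orthogonalised design.

    ``beta_draws``: (draws, species, columns); ``rho_draws``: (draws, J, J).
    The design's non-intercept columns are made exactly orthonormal so that
    analytically known environmental correlations hold to rounding error.
    """
    beta_draws = np.asarray(beta_draws, float)
    rho_draws = np.asarray(rho_draws, float)
    d, nsp, p = beta_draws.shape
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_sites, p - 1))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    values = np.column_stack([np.ones(n_sites), q])
    columns = ["intercept"] + [f"x{i}" for i in range(p - 1)]
    spec = ModelSpec("manual", [f"x{i}" for i in range(p - 1)],
                     [f"s{j}" for j in range(nsp)])
    design = DesignMatrix(values, columns, np.arange(n_sites), spec,
                          {c: 0.0 for c in columns[1:]},
                          {c: 1.0 for c in columns[1:]})
    if chain is None:
        chain = np.zeros(d, dtype=int)
        chain[d // 2:] = 1
    return JsdmPosterior(beta=beta_draws, rho=rho_draws,
                         chain=np.asarray(chain), spec=spec, design=design)
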