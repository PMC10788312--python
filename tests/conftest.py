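import numpy as np
import pytest

import compcost as cc


@pytest.fixture(scope="session")
def fig3_surface():
    """The worked-example surface -4x^2 - 4y^2 + 7xy (gamma = -8, -8, 7)."""
    return cc.QuadraticPerformanceSurface(gamma11=-8.0, gamma22=-8.0, gamma12=7.0)


@pytest.fixture(scope="session")
def grad10():
    return cc.SexualSelectionGradient(10.0)


@pytest.fixture(scope="session")
def calibrated_params():
    return cc.default_params()


@pytest.fixture(scope="session")
def synthetic_table(calibrated_params):
    return cc.generate_experiment(calibrated_params, cc.ExperimentDesign(), seed=7)


def simulate_lmm(
    seed,
    beta=(22.37, 0.96, 8.36),
    var_individual=0.20,
    var_residual=15.39,
    n_individuals=20,
):
    """Draw one dataset from the random-intercept quadratic LMM itself
    (z-scored five-level shortening design, one observation per cell)."""
    rng = np.random.default_rng(seed)
    treatments = np.tile([0.0, -20.0, -40.0, -60.0, -80.0], n_individuals)
    groups = np.repeat([f"ind{j}" for j in range(n_individuals)], 5)
    z = (treatments + 40.0) / np.sqrt(1000.0)
    X = np.column_stack([np.ones_like(z), z, z**2])
    u = rng.normal(0.0, np.sqrt(var_individual), n_individuals)
    y = X @ np.asarray(beta) + np.repeat(u, 5) + rng.normal(
        0.0, np.sqrt(var_residual), len(z)
    )
    return y, X, groups
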