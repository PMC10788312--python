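"""Bayesian random-intercept linear mixed model by conjugate Gibbs sampling.

Model for the averaged stability angles::

    y_ij = x_ij' beta + u_j + e_ij,   u_j ~ N(0, s2_u),  e_ij ~ N(0, s2_e)

with fixed effects beta (intercept, linear and quadratic terms of the
scaled manipulation predictor) under a vague normal prior, and both
variance components under weak inverse-gamma priors parameterized as an
inverse-Wishart with scale V and degree-of-belief nu (defaults V=1,
nu=0.002, i.e. shape nu/2 and rate nu*V/2).  All full conditionals are
conjugate, so the sampler is an exact Gibbs cycle; runs are reproducible
from a seed and multiple chains support the Brooks-Gelman-Rubin diagnostic.

The shape verdict turns the posterior into the scientific conclusion:
a positive quadratic coefficient with the fitted parabola's vertex inside
the manipulated range means the shortening experiment exhibits a concave
cost function (stability worsens on both sides of an interior optimum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import DesignMatrices, FIXED_EFFECT_NAMES

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "CostVerdict",
    "gibbs_lmm",
    "rhat",
    "p_mcmc",
    "summarize",
    "classify_fitted_cost",
    "mcse",
]

VARIANCE_NAMES = ("var_individual", "var_residual")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; the defaults emulate MCMCglmm's documented ones
    (13000 iterations, 3000 burn-in, thin 10, fixed-effect prior variance
    1e10, variance priors V=1, nu=0.002), with 3 chains so Rhat is defined."""

    n_iter: int = 13000
    burn_in: int = 3000
    thin: int = 10
    n_chains: int = 3
    seed: int | None = None
    prior_fixed_variance: float = 1e10
    prior_variance_v: float = 1.0
    prior_variance_nu: float = 0.002

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        for name in ("prior_fixed_variance", "prior_variance_v", "prior_variance_nu"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class PosteriorDraws:
    """Thinned post-burn-in draws, shaped (n_chains, n_draws[, n_params])."""

    fixed: np.ndarray
    var_individual: np.ndarray
    var_residual: np.ndarray
    fixed_names: tuple[str, ...] = FIXED_EFFECT_NAMES

    @property
    def n_chains(self) -> int:
        return self.fixed.shape[0]

    @property
    def n_draws(self) -> int:
        return self.fixed.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (n_chains, n_draws)."""
        if name in self.fixed_names:
            return self.fixed[:, :, self.fixed_names.index(name)]
        if name == "var_individual":
            return self.var_individual
        if name == "var_residual":
            return self.var_residual
        raise KeyError(name)

    def pooled(self, name: str) -> np.ndarray:
        return self.parameter(name).reshape(-1)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self.fixed_names) + VARIANCE_NAMES


def _sample_inverse_gamma(
    rng: np.random.Generator, shape: float, rate: float
) -> float:
    return rate / rng.gamma(shape)


def _run_chain(
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    config: MCMCConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, p = X.shape
    XtX = X.T @ X
    prior_prec = np.eye(p) / config.prior_fixed_variance
    a0 = config.prior_variance_nu / 2.0
    b0 = config.prior_variance_nu * config.prior_variance_v / 2.0
    counts = np.bincount(group_idx, minlength=n_groups).astype(float)

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    u = np.zeros(n_groups)
    var_e = max(float(np.var(y)), 1e-8)
    var_u = var_e / 2.0 + 1e-8

    n_kept = (config.n_iter - config.burn_in) // config.thin
    fixed_draws = np.empty((n_kept, p))
    var_u_draws = np.empty(n_kept)
    var_e_draws = np.empty(n_kept)

    kept = 0
    for it in range(config.n_iter):
        # fixed effects | u, variances: multivariate normal full conditional
        resid_u = y - u[group_idx]
        prec = XtX / var_e + prior_prec
        try:
            chol = np.linalg.cholesky(prec)
        except np.linalg.LinAlgError as err:
            raise ArithmeticError(
                f"non-positive-definite conditional at iteration {it}"
            ) from err
        rhs = X.T @ resid_u / var_e
        mean = np.linalg.solve(chol.T, np.linalg.solve(chol, rhs))
        beta = mean + np.linalg.solve(chol.T, rng.standard_normal(p))

        # group intercepts | beta: independent normal full conditionals
        resid_b = y - X @ beta
        sums = np.bincount(group_idx, weights=resid_b, minlength=n_groups)
        prec_u = counts / var_e + 1.0 / var_u
        mean_u = (sums / var_e) / prec_u
        u = mean_u + rng.standard_normal(n_groups) / np.sqrt(prec_u)

        # variance components | beta, u: inverse-gamma full conditionals
        var_u = _sample_inverse_gamma(
            rng, a0 + 0.5 * n_groups, b0 + 0.5 * float(u @ u)
        )
        resid = resid_b - u[group_idx]
        var_e = _sample_inverse_gamma(
            rng, a0 + 0.5 * n, b0 + 0.5 * float(resid @ resid)
        )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            fixed_draws[kept] = beta
            var_u_draws[kept] = var_u
            var_e_draws[kept] = var_e
            kept += 1
    return fixed_draws[:kept], var_u_draws[:kept], var_e_draws[:kept]


def gibbs_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    config: MCMCConfig | None = None,
    fixed_names: tuple[str, ...] | None = None,
) -> PosteriorDraws:
    """Sample the random-intercept LMM posterior; same seed, same draws."""
    config = config if config is not None else MCMCConfig()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one row per observation")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("X is rank deficient")
    labels, group_idx = np.unique(np.asarray(groups), return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups for a random intercept")
    if fixed_names is None:
        fixed_names = (
            FIXED_EFFECT_NAMES
            if X.shape[1] == len(FIXED_EFFECT_NAMES)
            else tuple(f"beta{j}" for j in range(X.shape[1]))
        )
    seed_seq = np.random.SeedSequence(config.seed)
    chain_seeds = seed_seq.spawn(config.n_chains)
    fixed, var_u, var_e = [], [], []
    for child in chain_seeds:
        rng = np.random.default_rng(child)
        f, vu, ve = _run_chain(y, X, group_idx, len(labels), config, rng)
        fixed.append(f)
        var_u.append(vu)
        var_e.append(ve)
    return PosteriorDraws(
        fixed=np.stack(fixed),
        var_individual=np.stack(var_u),
        var_residual=np.stack(var_e),
        fixed_names=tuple(fixed_names),
    )


def rhat(chains: np.ndarray) -> float:
    """Brooks-Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  Computed as
    sqrt(((n-1)/n * W + B/n) / W) from the within-chain variance W and the
    between-chain variance B = n * var(chain means).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a 2-D (n_chains, n_draws) array")
    m, n = chains.shape
    if m < 2:
        raise ValueError("need >= 2 chains for Rhat")
    if n < 10:
        raise ValueError("need >= 10 draws per chain")
    w = float(np.mean(np.var(chains, axis=1, ddof=1)))
    b_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else math.inf
    var_plus = (n - 1) / n * w + b_over_n
    return math.sqrt(var_plus / w)


def p_mcmc(draws: np.ndarray) -> float:
    """MCMC two-sided sign probability: 2*min(Pr(>0), Pr(<0)), floored
    at 1/n_draws (a chain can never certify an exact zero)."""
    draws = np.asarray(draws, dtype=float).reshape(-1)
    n = draws.size
    if n < 100:
        raise ValueError("need >= 100 draws for a stable tail probability")
    p = 2.0 * min(float(np.mean(draws > 0)), float(np.mean(draws < 0)))
    return float(min(max(p, 1.0 / n), 1.0))


def mcse(draws: np.ndarray, n_batches: int = 20) -> float:
    """Monte-Carlo standard error of the mean by the batch-means method."""
    draws = np.asarray(draws, dtype=float).reshape(-1)
    n = draws.size
    if n < 2 * n_batches:
        raise ValueError("too few draws for batch means")
    batch = n // n_batches
    means = draws[: batch * n_batches].reshape(n_batches, batch).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_batches))


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, 95% credible interval, pMCMC and Rhat per parameter.

    pMCMC is reported for fixed effects only (variances are positive by
    construction); Rhat requires >= 2 chains and is NaN otherwise.
    """
    rows = []
    for name in draws.parameter_names:
        chains = draws.parameter(name)
        pooled = chains.reshape(-1)
        lo, hi = np.percentile(pooled, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p_mcmc": p_mcmc(pooled) if name in draws.fixed_names else np.nan,
                "rhat": rhat(chains) if draws.n_chains >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


@dataclass(frozen=True)
class CostVerdict:
    """Posterior verdict on the shape of the manipulation response."""

    verdict: str
    prob_concave: float
    prob_incremental: float
    vertex_mean: float = field(default=np.nan)

    CONCAVE = "concave_cost"
    INCREMENTAL = "incremental_cost"
    INCONCLUSIVE = "inconclusive"


def classify_fitted_cost(
    draws: PosteriorDraws,
    predictor_range: tuple[float, float],
    prob_threshold: float = 0.95,
) -> CostVerdict:
    """Decide concave vs incremental cost from the posterior of the fit.

    Per draw the fitted angle curve a + b*z + c*z**2 has its vertex at
    z* = -b/(2c).  A draw supports a concave cost when the curve is convex
    in the angle (c > 0) with the vertex strictly inside the manipulated
    range.  The verdict requires posterior probability >= ``prob_threshold``
    either way; otherwise the data are inconclusive.
    """
    names = draws.fixed_names
    if "linear" not in names or "quadratic" not in names:
        raise ValueError("draws must include 'linear' and 'quadratic' effects")
    lo, hi = predictor_range
    b = draws.pooled("linear")
    c = draws.pooled("quadratic")
    with np.errstate(divide="ignore", invalid="ignore"):
        vertex = np.where(c != 0, -b / (2.0 * c), np.inf)
    concave = (c > 0) & (vertex > lo) & (vertex < hi)
    prob_concave = float(np.mean(concave))
    prob_incremental = 1.0 - prob_concave
    if prob_concave >= prob_threshold:
        verdict = CostVerdict.CONCAVE
    elif prob_incremental >= prob_threshold:
        verdict = CostVerdict.INCREMENTAL
    else:
        verdict = CostVerdict.INCONCLUSIVE
    vertex_interior = vertex[np.isfinite(vertex)]
    return CostVerdict(
        verdict=verdict,
        prob_concave=prob_concave,
        prob_incremental=prob_incremental,
        vertex_mean=float(vertex_interior.mean()) if vertex_interior.size else np.nan,
    )
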