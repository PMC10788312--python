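"""Gibbs sampler correctness, diagnostics and the posterior shape verdict."""

import numpy as np
import pytest

import compcost as cc
from compcost.inference import (
    MCMCConfig,
    PosteriorDraws,
    classify_fitted_cost,
    mcse,
    p_mcmc,
    rhat,
)
from conftest import simulate_lmm


class TestPMCMC:
    def test_all_positive_hits_floor(self):
        assert p_mcmc(np.ones(1000)) == pytest.approx(1 / 1000)

    def test_symmetric_draws_near_one(self):
        draws = np.concatenate([np.ones(500), -np.ones(500)])
        assert p_mcmc(draws) == pytest.approx(1.0)

    def test_arithmetic(self):
        draws = np.concatenate([np.ones(975), -np.ones(25)])
        assert p_mcmc(draws) == pytest.approx(0.05)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            p_mcmc(np.ones(50))


class TestRhat:
    def test_duplicated_chains(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=1000)
        assert rhat(np.stack([chain, chain])) <= 1.0 + 1e-12

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(1)
        chains = np.stack(
            [rng.normal(0.0, 1.0, 1000), rng.normal(10.0, 1.0, 1000)]
        )
        assert rhat(chains) > 5.0

    def test_closed_form_plugin(self):
        # two interleaved +-1 chains shifted by 0 and 10: W and B computable
        base = np.tile([1.0, -1.0], 500)
        chains = np.stack([base, base + 10.0])
        n = 1000
        w = base.var(ddof=1)
        b_over_n = np.var([0.0, 10.0], ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b_over_n) / w)
        assert rhat(chains) == pytest.approx(expected)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 100)))


class TestGibbs:
    def test_same_seed_identical_draws(self):
        y, X, groups = simulate_lmm(seed=5)
        cfg = MCMCConfig(n_iter=1500, burn_in=500, thin=5, n_chains=2, seed=9)
        d1 = cc.gibbs_lmm(y, X, groups, cfg)
        d2 = cc.gibbs_lmm(y, X, groups, cfg)
        np.testing.assert_array_equal(d1.fixed, d2.fixed)
        np.testing.assert_array_equal(d1.var_residual, d2.var_residual)

    def test_intercept_only_recovers_grand_mean(self):
        y, _, groups = simulate_lmm(seed=6)
        X = np.ones((len(y), 1))
        cfg = MCMCConfig(seed=10, n_chains=1)
        draws = cc.gibbs_lmm(y, X, groups, cfg)
        post_mean = float(draws.fixed.mean())
        assert post_mean == pytest.approx(
            float(np.mean(y)), abs=4 * mcse(draws.fixed.reshape(-1)) + 0.05
        )

    def test_no_group_signal_shrinks_variance(self):
        y, X, groups = simulate_lmm(seed=7, var_individual=0.0)
        draws = cc.gibbs_lmm(y, X, groups, MCMCConfig(seed=11, n_chains=1))
        var_ind = draws.pooled("var_individual")
        var_res = draws.pooled("var_residual")
        assert np.percentile(var_ind, 2.5) < 0.1 * var_res.mean()
        assert var_ind.mean() < 0.2 * var_res.mean()

    def test_posterior_means_match_gls(self):
        """Balanced design: GLS (= OLS here) is the oracle for fixed effects."""
        y, X, groups = simulate_lmm(seed=8, var_individual=1.0, var_residual=4.0)
        draws = cc.gibbs_lmm(y, X, groups, MCMCConfig(seed=12))
        gls = np.linalg.lstsq(X, y, rcond=None)[0]
        for j in range(3):
            pooled = draws.fixed[:, :, j].reshape(-1)
            tol = 3.0 * mcse(pooled)
            assert pooled.mean() == pytest.approx(gls[j], abs=max(tol, 0.02))

    def test_posterior_means_match_mixedlm(self):
        """Cross-check against the REML mixed-model fit in statsmodels."""
        import statsmodels.api as sm

        y, X, groups = simulate_lmm(seed=13, n_individuals=30)
        draws = cc.gibbs_lmm(y, X, groups, MCMCConfig(seed=14, n_chains=2))
        fit = sm.MixedLM(y, X, groups=np.asarray(groups)).fit()
        np.testing.assert_allclose(
            draws.fixed.reshape(-1, 3).mean(axis=0), fit.fe_params, atol=0.2
        )

    def test_parameter_recovery_within_three_sd(self):
        truth = np.array([20.0, 1.0, 8.0])
        y, X, groups = simulate_lmm(
            seed=15, beta=truth, var_individual=0.2, var_residual=15.0
        )
        draws = cc.gibbs_lmm(y, X, groups, MCMCConfig(seed=16, n_chains=1))
        flat = draws.fixed.reshape(-1, 3)
        for j in range(3):
            sd = flat[:, j].std(ddof=1)
            assert abs(flat[:, j].mean() - truth[j]) < 3.0 * sd

    def test_rank_deficient_rejected(self):
        y, X, groups = simulate_lmm(seed=17)
        X_bad = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank"):
            cc.gibbs_lmm(y, X_bad, groups, MCMCConfig(seed=1))


class TestSummary:
    def test_summary_layout_and_interval_order(self):
        y, X, groups = simulate_lmm(seed=18)
        draws = cc.gibbs_lmm(
            y, X, groups, MCMCConfig(n_iter=3000, burn_in=1000, seed=19)
        )
        summary = cc.summarize(draws)
        assert list(summary.index) == [
            "intercept",
            "linear",
            "quadratic",
            "var_individual",
            "var_residual",
        ]
        assert (summary["ci_low"] <= summary["mean"]).all()
        assert (summary["mean"] <= summary["ci_high"]).all()
        assert summary.loc["var_individual", "ci_low"] > 0
        assert np.isnan(summary.loc["var_residual", "p_mcmc"])


class TestVerdict:
    def _draws(self, b_lin, b_quad, n=200):
        fixed = np.tile([10.0, b_lin, b_quad], (1, n, 1))
        return PosteriorDraws(
            fixed=fixed,
            var_individual=np.ones((1, n)),
            var_residual=np.ones((1, n)),
        )

    def test_degenerate_concave_draws(self):
        # vertex at -(-2)/(2*4) = 0.25, inside the range
        verdict = classify_fitted_cost(self._draws(-2.0, 4.0), (-1.3, 1.3))
        assert verdict.verdict == "concave_cost"
        assert verdict.prob_concave == 1.0

    def test_negative_quadratic_is_incremental(self):
        verdict = classify_fitted_cost(self._draws(1.0, -4.0), (-1.3, 1.3))
        assert verdict.verdict == "incremental_cost"

    def test_exterior_vertex_is_incremental(self):
        verdict = classify_fitted_cost(self._draws(-20.0, 1.0), (-1.3, 1.3))
        assert verdict.verdict == "incremental_cost"

    def test_missing_quadratic_rejected(self):
        draws = PosteriorDraws(
            fixed=np.ones((1, 200, 1)),
            var_individual=np.ones((1, 200)),
            var_residual=np.ones((1, 200)),
            fixed_names=("intercept",),
        )
        with pytest.raises(ValueError):
            classify_fitted_cost(draws, (-1.0, 1.0))

    def test_flat_truth_rarely_declared_concave(self):
        """Type-I behaviour: with no true curvature the 0.95 posterior rule
        should almost never return a concave verdict."""
        false_concave = 0
        n_reps = 100
        for rep in range(n_reps):
            y, X, groups = simulate_lmm(
                seed=1000 + rep,
                beta=(20.0, 1.0, 0.0),
                var_individual=0.2,
                var_residual=15.0,
                n_individuals=4,
            )
            cfg_rep = MCMCConfig(
                n_iter=2000, burn_in=500, thin=5, n_chains=1, seed=rep
            )
            draws = cc.gibbs_lmm(y, X, groups, cfg_rep)
            verdict = classify_fitted_cost(draws, (-1.2649, 1.2649))
            if verdict.verdict == "concave_cost":
                false_concave += 1
        assert false_concave <= 0.05 * n_reps
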