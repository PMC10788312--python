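"""Evolved current state, manipulation paths, and the discrete toy game."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

import compcost as cc
from compcost.selection import UnboundedFitnessError


def grid_refine_argmax(objective, bounds=(-20.0, 20.0), n=401):
    """Independent oracle: dense grid then local refinement of a 2-D max."""
    axis = np.linspace(*bounds, n)
    xx, yy = np.meshgrid(axis, axis)
    values = objective(xx, yy)
    start = np.array([xx.ravel()[values.argmax()], yy.ravel()[values.argmax()]])
    res = minimize(lambda p: -objective(p[0], p[1]), start, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12})
    return res.x


elliptical_surfaces = st.builds(
    lambda g11, g22, rho: cc.QuadraticPerformanceSurface(
        g11, g22, rho * np.sqrt(g11 * g22)
    ),
    g11=st.floats(-10.0, -0.5),
    g22=st.floats(-10.0, -0.5),
    rho=st.floats(0.05, 0.95),
)


class TestCurrentState:
    def test_worked_example(self, fig3_surface, grad10):
        x1, x2 = cc.current_state(fig3_surface, grad10)
        assert x1 == pytest.approx(16.0 / 3.0)
        assert x2 == pytest.approx(14.0 / 3.0)

    def test_matches_numeric_maximization(self, fig3_surface, grad10):
        oracle = grid_refine_argmax(
            lambda x, y: cc.evaluate_performance(fig3_surface, x, y)
            + grad10.s * x
        )
        x1, x2 = cc.current_state(fig3_surface, grad10)
        assert x1 == pytest.approx(oracle[0], abs=1e-6)
        assert x2 == pytest.approx(oracle[1], abs=1e-6)

    def test_no_selection_recovers_peak(self, fig3_surface):
        assert cc.current_state(
            fig3_surface, cc.SexualSelectionGradient(0.0)
        ) == pytest.approx((0.0, 0.0))

    def test_decoupled_axes(self):
        surf = cc.QuadraticPerformanceSurface(-2.0, -2.0, 0.0)
        x1, x2 = cc.current_state(surf, cc.SexualSelectionGradient(4.0))
        assert (x1, x2) == pytest.approx((2.0, 0.0))

    def test_saddle_rejected(self, grad10):
        with pytest.raises(UnboundedFitnessError):
            cc.current_state(
                cc.QuadraticPerformanceSurface(-2.0, -2.0, 3.0), grad10
            )

    @settings(max_examples=100, derandomize=True)
    @given(surf=elliptical_surfaces, s=st.floats(0.1, 20.0))
    def test_compensation_on_ridge(self, surf, s):
        x1, x2 = cc.current_state(surf, cc.SexualSelectionGradient(s))
        assert x2 == pytest.approx(
            cc.ridge_compensation(surf, x1), abs=1e-9, rel=1e-9
        )

    @settings(max_examples=50, derandomize=True)
    @given(surf=elliptical_surfaces)
    def test_ornament_monotone_in_selection(self, surf):
        states = [
            cc.current_state(surf, cc.SexualSelectionGradient(s))[0]
            for s in (0.0, 1.0, 5.0, 10.0, 20.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(states, states[1:]))


class TestManipulationPath:
    def test_peak_matches_conditional_curve(self, fig3_surface, grad10):
        x1_star, x2_star = cc.current_state(fig3_surface, grad10)
        curve = cc.conditional_cost_curve(fig3_surface, x2_star)
        path = cc.manipulation_path(
            fig3_surface, grad10, np.linspace(0.0, x1_star, 1601)
        )
        best_x1 = path.loc[path["performance"].idxmax(), "x1"]
        assert best_x1 == pytest.approx(curve.peak_x1, abs=x1_star / 1600)
        assert curve.peak_x1 == pytest.approx(49.0 / 12.0)

    def test_zero_delta_is_current_performance(self, fig3_surface, grad10):
        x1, x2 = cc.current_state(fig3_surface, grad10)
        path = cc.manipulation_path(fig3_surface, grad10, [0.0])
        assert path["performance"].iloc[0] == pytest.approx(
            cc.evaluate_performance(fig3_surface, x1, x2)
        )

    def test_no_selection_path_declines(self, fig3_surface):
        grad = cc.SexualSelectionGradient(0.0)
        path = cc.manipulation_path(fig3_surface, grad, [0.0, 0.5, 1.0, 2.0])
        perf = path["performance"].to_numpy()
        assert np.all(np.diff(perf) < 0)

    def test_empty_deltas(self, fig3_surface, grad10):
        assert cc.manipulation_path(fig3_surface, grad10, []).empty

    def test_cost_nonnegative(self, fig3_surface, grad10):
        path = cc.manipulation_path(fig3_surface, grad10, np.linspace(0, 5, 21))
        assert (path["cost"] >= -1e-12).all()

    @settings(max_examples=100, derandomize=True)
    @given(surf=elliptical_surfaces, s=st.floats(0.1, 20.0))
    def test_interior_peak_fraction(self, surf, s):
        """The path peak sits at (g12^2/(g11*g22)) * x1_star, inside
        (0, x1_star): a concave cost function is guaranteed in the regime."""
        grad = cc.SexualSelectionGradient(s)
        x1_star, x2_star = cc.current_state(surf, grad)
        peak = cc.conditional_cost_curve(surf, x2_star).peak_x1
        frac = surf.gamma12**2 / (surf.gamma11 * surf.gamma22)
        assert peak == pytest.approx(frac * x1_star, rel=1e-9)
        assert 0.0 < peak < x1_star


class TestToyGame:
    def test_default_game_unique_ess(self, calibrated_params):
        ess = cc.solve_toy_game(
            cc.default_strategy_grid(),
            cc.tilt_model(calibrated_params),
            calibrated_params.cutoff_deg,
        )
        assert ess == {cc.ToyStrategy(110.0, wings=True)}

    def test_zero_cutoff_extinction(self, calibrated_params):
        with pytest.warns(UserWarning, match="extinct"):
            ess = cc.solve_toy_game(
                cc.default_strategy_grid(),
                cc.tilt_model(calibrated_params),
                0.0,
            )
        assert ess == set()

    def test_single_ancestral_strategy_survives(self, calibrated_params):
        ancestral = cc.ToyStrategy(0.0, wings=False)
        ess = cc.solve_toy_game(
            [ancestral], cc.tilt_model(calibrated_params), 30.0
        )
        assert ess == {ancestral}

    def test_empty_strategy_list_rejected(self, calibrated_params):
        with pytest.raises(ValueError):
            cc.solve_toy_game([], cc.tilt_model(calibrated_params), 30.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_enumeration(self, seed):
        """Cross-check against a separately coded filter-then-argmax."""
        rng = np.random.default_rng(seed)
        strategies = [
            cc.ToyStrategy(float(e), bool(w))
            for e, w in zip(
                rng.integers(0, 12, 30) * 10.0, rng.integers(0, 2, 30)
            )
        ]
        tilts = {s: float(t) for s, t in zip(strategies, rng.normal(0, 40, 30))}
        cutoff = 30.0
        alive = {s for s in strategies if abs(tilts[s]) < cutoff}
        expected = (
            {
                s
                for s in alive
                if s.tail_elongation_mm
                == max(a.tail_elongation_mm for a in alive)
            }
            if alive
            else set()
        )
        if expected:
            got = cc.solve_toy_game(strategies, tilts.get, cutoff)
        else:
            with pytest.warns(UserWarning):
                got = cc.solve_toy_game(strategies, tilts.get, cutoff)
        assert got == expected
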