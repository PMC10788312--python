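"""Locating the evolved phenotype and solving the toy survival/mating game.

Two routes to the "current state" of an ornamented animal:

* continuous: add a linear sexual-selection surface ``s*x1`` to a quadratic
  performance surface and maximize the sum (`current_state`), then trace the
  phenotypes visited by an ornament-shortening experiment
  (`manipulation_path`);
* discrete: enumerate balancing-toy morphs, keep those stable enough to
  "survive" a tilt cutoff, and let the longest-tailed survivor "reproduce"
  (`solve_toy_game`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .surfaces import (
    QuadraticPerformanceSurface,
    SurfaceGeometry,
    classify_geometry,
    evaluate_performance,
)

__all__ = [
    "SexualSelectionGradient",
    "ToyStrategy",
    "UnboundedFitnessError",
    "current_state",
    "manipulation_path",
    "solve_toy_game",
    "default_strategy_grid",
]


class UnboundedFitnessError(ValueError):
    """Performance + sexual selection has no finite maximum."""


@dataclass(frozen=True)
class SexualSelectionGradient:
    """Linear mating-advantage gradient on the ornament axis (s >= 0)."""

    s: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.s):
            raise ValueError("s must be finite")
        if self.s < 0:
            raise ValueError("s must be non-negative")


@dataclass(frozen=True)
class ToyStrategy:
    """A balancing-toy morph: added tail length and wings on/off."""

    tail_elongation_mm: float
    wings: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.tail_elongation_mm):
            raise ValueError("tail_elongation_mm must be finite")
        if self.tail_elongation_mm < 0:
            raise ValueError("tail_elongation_mm must be >= 0")


def default_strategy_grid(
    max_elongation_mm: float = 110.0, step_mm: float = 10.0
) -> list[ToyStrategy]:
    """All (elongation, wings) morphs on the default 0..110 mm grid."""
    lengths = np.arange(0.0, max_elongation_mm + 0.5 * step_mm, step_mm)
    return [
        ToyStrategy(tail_elongation_mm=float(length), wings=wings)
        for length in lengths
        for wings in (False, True)
    ]


def current_state(
    surface: QuadraticPerformanceSurface, grad: SexualSelectionGradient
) -> tuple[float, float]:
    """Maximizer of performance + s*x1 on an elliptical surface.

    Solves the stationarity system::

        g11*x1 + g12*x2 + b1 + s = 0
        g12*x1 + g22*x2 + b2     = 0

    With s > 0, g12 > 0 and b = 0 the solution lies to the right of the
    performance peak with compensation tuned to the ornament (on the ridge
    line) -- the evolved state a manipulation experiment starts from.
    """
    if classify_geometry(surface) is not SurfaceGeometry.ELLIPTICAL_PEAK:
        raise UnboundedFitnessError(
            "performance + sexual selection is unbounded unless the "
            "surface is an elliptical peak"
        )
    rhs = -(surface.beta_vector + np.array([grad.s, 0.0]))
    x = np.linalg.solve(surface.gamma_matrix, rhs)
    return float(x[0]), float(x[1])


def manipulation_path(
    surface: QuadraticPerformanceSurface,
    grad: SexualSelectionGradient,
    deltas: Iterable[float],
) -> pd.DataFrame:
    """Phenotypes visited when the ornament is reduced by each delta >= 0.

    Compensation stays frozen at the evolved level x2*; each row gives the
    manipulated ornament value, the performance there, and the cost measured
    as the surface's best achievable performance minus that performance.
    """
    deltas = np.asarray(list(deltas), dtype=float)
    if deltas.size == 0:
        return pd.DataFrame(columns=["delta", "x1", "performance", "cost"])
    if np.any(deltas < 0):
        raise ValueError("deltas are ornament reductions and must be >= 0")
    x1_star, x2_star = current_state(surface, grad)
    x1 = x1_star - deltas
    performance = evaluate_performance(surface, x1, np.full_like(x1, x2_star))
    performance = np.atleast_1d(performance)
    best = evaluate_performance(surface, *surface.global_maximum())
    return pd.DataFrame(
        {
            "delta": deltas,
            "x1": x1,
            "performance": performance,
            "cost": best - performance,
        }
    )


def solve_toy_game(
    strategies: Sequence[ToyStrategy],
    tilt_model: Callable[[ToyStrategy], float],
    cutoff_deg: float = 30.0,
) -> set[ToyStrategy]:
    """ESS morphs of the survive-then-reproduce game.

    A morph survives iff its deterministic tilt is within ``cutoff_deg`` of
    horizontal; among survivors only the longest-tailed reproduce.  Returns
    the set of survivors with maximal tail elongation (a set, to keep ties
    explicit).  An empty strategy list is an error; a game with no survivors
    returns an empty set with a warning (the population is extinct).
    """
    strategies = list(strategies)
    if not strategies:
        raise ValueError("strategies must be non-empty")
    if not cutoff_deg >= 0:
        raise ValueError("cutoff_deg must be >= 0")
    survivors = [s for s in strategies if abs(tilt_model(s)) < cutoff_deg]
    if not survivors:
        warnings.warn(
            "no strategy survives the balance cutoff: population extinct",
            stacklevel=2,
        )
        return set()
    longest = max(s.tail_elongation_mm for s in survivors)
    return {s for s in survivors if s.tail_elongation_mm == longest}
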