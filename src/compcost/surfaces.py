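"""Bivariate quadratic performance surfaces and manipulation cost curves.

The central object is a Lande–Arnold style quadratic approximation to a
whole-organism performance surface over an ornament axis ``x1`` and a
compensatory-trait axis ``x2``::

    w(x1, x2) = 0.5*g11*x1**2 + b1*x1 + 0.5*g22*x2**2 + b2*x2 + g12*x1*x2 + a

with curvatures ``g11, g22`` (negative on a hill), interaction ``g12``
(positive when the second trait compensates for the first) and linear
gradients ``b1, b2``.  Experimentally shortening the ornament while the
compensatory trait stays frozen at its evolved level ``k`` traces the 1-D
conditional curve ``w(x1, k)``, whose peak location decides whether the
manipulation reveals a concave or an incremental cost function.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuadraticPerformanceSurface",
    "ConditionalCostCurve",
    "SurfaceGeometry",
    "CostShape",
    "InvalidSurfaceError",
    "DegenerateCurveError",
    "NoInteriorMaximumError",
    "evaluate_performance",
    "classify_geometry",
    "ridge_compensation",
    "conditional_cost_curve",
    "classify_cost_shape",
]


class InvalidSurfaceError(ValueError):
    """A surface coefficient or coordinate is not a finite number."""


class DegenerateCurveError(ValueError):
    """The conditional curve has no quadratic term (gamma11 == 0)."""


class NoInteriorMaximumError(ValueError):
    """Performance does not peak at an interior compensation value."""


class SurfaceGeometry(enum.Enum):
    """Shape classes of a negatively curved quadratic surface."""

    ELLIPTICAL_PEAK = "elliptical_peak"
    SADDLE = "saddle"
    PERFECT_COMPENSATION_RIDGE = "perfect_compensation_ridge"
    NOT_APPLICABLE = "not_applicable"


class CostShape(enum.Enum):
    """Qualitative verdict on the cost function revealed by shortening.

    ``CONCAVE``     -- performance first rises then falls as the ornament is
                       reduced (interior peak; U-shaped cost).
    ``INCREMENTAL`` -- performance rises all the way to zero ornament.
    ``DECREASING``  -- performance falls monotonically under shortening
                       (peak at or beyond the current expression).
    ``FLAT``        -- the conditional curve is constant to tolerance.
    """

    CONCAVE = "concave"
    INCREMENTAL = "incremental"
    DECREASING = "decreasing"
    FLAT = "flat"


def _require_finite(**values: float) -> None:
    for name, value in values.items():
        if not math.isfinite(value):
            raise InvalidSurfaceError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class QuadraticPerformanceSurface:
    """Coefficients of the bivariate quadratic performance function.

    Parameters
    ----------
    gamma11, gamma22
        Curvature along the ornament (x1) and compensation (x2) axes;
        both negative on a performance hill.
    gamma12
        Interaction curvature; positive when x2 compensates x1.
    beta1, beta2
        Linear selection gradients (zero in the canonical hill centred at
        the origin).
    alpha
        Constant offset.
    """

    gamma11: float
    gamma22: float
    gamma12: float
    beta1: float = 0.0
    beta2: float = 0.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(
            gamma11=self.gamma11,
            gamma22=self.gamma22,
            gamma12=self.gamma12,
            beta1=self.beta1,
            beta2=self.beta2,
            alpha=self.alpha,
        )

    @property
    def gamma_matrix(self) -> np.ndarray:
        """The symmetric curvature matrix [[g11, g12], [g12, g22]]."""
        return np.array(
            [[self.gamma11, self.gamma12], [self.gamma12, self.gamma22]]
        )

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta1, self.beta2])

    def in_concave_regime(self) -> bool:
        """True in the compensated-ornament regime: g11<0, g22<0, g12>0."""
        return self.gamma11 < 0 and self.gamma22 < 0 and self.gamma12 > 0

    def evaluate(self, x1, x2):
        return evaluate_performance(self, x1, x2)

    def global_maximum(self) -> tuple[float, float]:
        """Stationary point of the surface; unique maximum when elliptical.

        Raises
        ------
        NoInteriorMaximumError
            If the surface is not an elliptical peak (saddle or degenerate
            curvature), where no interior maximum exists.
        """
        if classify_geometry(self) is not SurfaceGeometry.ELLIPTICAL_PEAK:
            raise NoInteriorMaximumError(
                "surface has no interior maximum (not an elliptical peak)"
            )
        x = np.linalg.solve(self.gamma_matrix, -self.beta_vector)
        return float(x[0]), float(x[1])

    def to_dict(self) -> dict[str, float]:
        return {
            "gamma11": self.gamma11,
            "gamma22": self.gamma22,
            "gamma12": self.gamma12,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, entries: dict) -> "QuadraticPerformanceSurface":
        known = {"gamma11", "gamma22", "gamma12", "beta1", "beta2", "alpha"}
        unknown = set(entries) - known
        if unknown:
            raise InvalidSurfaceError(
                f"unknown surface coefficients: {sorted(unknown)}"
            )
        return cls(**{k: float(v) for k, v in entries.items()})


def evaluate_performance(
    surface: QuadraticPerformanceSurface, x1, x2
):
    """Evaluate the quadratic performance surface at (x1, x2).

    Accepts scalars or numpy arrays (broadcast together).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise InvalidSurfaceError("coordinates must be finite")
    value = (
        0.5 * surface.gamma11 * x1**2
        + surface.beta1 * x1
        + 0.5 * surface.gamma22 * x2**2
        + surface.beta2 * x2
        + surface.gamma12 * x1 * x2
        + surface.alpha
    )
    if value.ndim == 0:
        return float(value)
    return value


def classify_geometry(
    surface: QuadraticPerformanceSurface, rel_tol: float = 1e-9
) -> SurfaceGeometry:
    """Classify a negatively curved surface as peak, saddle or ridge.

    The discriminant g12**2 - g11*g22 separates an elliptical peak
    (negative) from a saddle (positive); equality -- compared with relative
    tolerance ``rel_tol`` because exact equality is measure-zero -- is the
    perfect-compensation ridge along which ornament growth can be fully
    offset.  Surfaces without negative curvature on both axes are
    ``NOT_APPLICABLE``.
    """
    if not (surface.gamma11 < 0 and surface.gamma22 < 0):
        return SurfaceGeometry.NOT_APPLICABLE
    lhs = surface.gamma12**2
    rhs = surface.gamma11 * surface.gamma22
    scale = max(abs(lhs), abs(rhs))
    if abs(lhs - rhs) <= rel_tol * scale:
        return SurfaceGeometry.PERFECT_COMPENSATION_RIDGE
    if lhs < rhs:
        return SurfaceGeometry.ELLIPTICAL_PEAK
    return SurfaceGeometry.SADDLE


def ridge_compensation(surface: QuadraticPerformanceSurface, x1: float) -> float:
    """Compensation level maximizing performance at a fixed ornament value.

    This is the ridge line of the surface: x2*(x1) = -(g12*x1 + b2)/g22.
    """
    if surface.gamma22 >= 0:
        raise NoInteriorMaximumError(
            "gamma22 must be negative for an interior compensation optimum"
        )
    return -(surface.gamma12 * x1 + surface.beta2) / surface.gamma22


@dataclass(frozen=True)
class ConditionalCostCurve:
    """The 1-D quadratic in ornament obtained by freezing compensation at k.

    Coefficients satisfy curve(x1) = a*x1**2 + b*x1 + c with
    a = 0.5*g11, b = g12*k + b1, c = 0.5*g22*k**2 + b2*k + alpha.
    ``peak_x1`` is the unique maximizer when g11 < 0.
    """

    a: float
    b: float
    c: float
    k: float
    peak_x1: float = field(init=False)

    def __post_init__(self) -> None:
        _require_finite(a=self.a, b=self.b, c=self.c, k=self.k)
        gamma11 = 2.0 * self.a
        if gamma11 == 0.0:
            raise DegenerateCurveError("gamma11 == 0: curve has no peak")
        object.__setattr__(self, "peak_x1", -self.b / gamma11)

    def evaluate(self, x1):
        x1 = np.asarray(x1, dtype=float)
        value = self.a * x1**2 + self.b * x1 + self.c
        if value.ndim == 0:
            return float(value)
        return value


def conditional_cost_curve(
    surface: QuadraticPerformanceSurface, k: float
) -> ConditionalCostCurve:
    """Freeze the compensatory trait at k and return the curve in x1.

    This models the manipulation experiment: the researcher changes the
    ornament while the animal's compensatory traits stay at their evolved
    value k.  The peak lies at -(g12*k + b1)/g11, strictly positive whenever
    k > 0, g12 > 0 and g11 < 0 -- the compensated regime, in which shortening
    the ornament first improves and then worsens performance.
    """
    if not math.isfinite(k):
        raise InvalidSurfaceError("k must be finite")
    if surface.gamma11 == 0.0:
        raise DegenerateCurveError("gamma11 == 0: conditional curve degenerate")
    return ConditionalCostCurve(
        a=0.5 * surface.gamma11,
        b=surface.gamma12 * k + surface.beta1,
        c=0.5 * surface.gamma22 * k**2 + surface.beta2 * k + surface.alpha,
        k=k,
    )


def classify_cost_shape(
    curve: ConditionalCostCurve, x1_current: float, tol: float = 1e-12
) -> CostShape:
    """Classify the cost function a shortening experiment would reveal.

    ``x1_current`` is the ornament expression before manipulation (must be
    positive).  A peak strictly inside (0, x1_current) means a concave cost
    function; a peak at or below zero means the classical incremental cost;
    a peak at or beyond the current expression means performance only falls
    under shortening; a curve with negligible coefficients is flat.
    """
    if not x1_current > 0:
        raise ValueError("x1_current must be positive")
    if abs(curve.a) <= tol and abs(curve.b) <= tol:
        return CostShape.FLAT
    if curve.peak_x1 <= 0:
        return CostShape.INCREMENTAL
    if curve.peak_x1 < x1_current:
        return CostShape.CONCAVE
    return CostShape.DECREASING
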