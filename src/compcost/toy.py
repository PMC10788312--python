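"""Synthetic balancing-toy experiment generator.

A torque-balance stand-in for the physical "chuonchuon" (a Vietnamese
balancing toy): a straw tail glued behind the pivot adds a tail-heavy
moment, clay wings ahead of the pivot add a compensating moment, and the
toy's resting tilt grows with the net moment.  The generator is calibrated
so that three reference morphs reproduce the study's printed mean tilts --
the ancestral toy (~4.9 deg), the fully elongated winged form (~22.4 deg)
and a wingless form with 30 mm of tail (~36.6 deg) -- and then emits a
long-format measurement table (individuals x shortening treatments x
replicate photos) with individual baseline effects and photo noise.

Model, in degrees::

    tilt  = angle_scale * (tail_moment - wing_moment + baseline_moment)
            + individual_effect + photo_noise
    angle = min(|tilt|, 90)

Tail moment = (remaining straw mass) * tail_arm_mm, with straw mass
proportional to remaining added length (uniform density).  The lumped
lever arm is held fixed as the tail is shortened; the arms are calibration
parameters, not measurements of the physical toy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .selection import ToyStrategy

__all__ = [
    "ToyPhysicalParams",
    "ExperimentDesign",
    "CalibrationError",
    "DEFAULT_ANCHORS",
    "net_moment",
    "tilt_angle",
    "tilt_model",
    "calibrate_generator",
    "default_params",
    "generate_experiment",
    "EXPERIMENT_COLUMNS",
]

#: Printed mean tilt (degrees) of the three calibration morphs:
#: the unmodified toy, the full ESS form (110 mm tail + wings), and the
#: wingless form with 30 mm of tail (manipulation -80 without wings).
DEFAULT_ANCHORS: Mapping[str, float] = {
    "ancestral": 4.87,
    "ess_full": 22.37,
    "wingless_30mm": 36.60,
}

EXPERIMENT_COLUMNS = ["individual_id", "treatment_mm", "replicate", "angle_deg"]


class CalibrationError(ValueError):
    """The anchor set cannot be met by the torque-balance model."""


@dataclass(frozen=True)
class ToyPhysicalParams:
    """Constants of the torque-balance toy model.

    Masses in grams, lengths in mm, moments in g*mm, angles in degrees.
    ``angle_scale_deg_per_gmm``, ``wing_arm_mm`` and ``baseline_moment_gmm``
    are the free calibration parameters; the defaults reproduce the three
    anchor means exactly (see `calibrate_generator`).
    """

    straw_mass_g: float = 0.4
    straw_length_mm: float = 160.0
    full_elongation_mm: float = 110.0
    wing_mass_g: float = 0.8
    tail_arm_mm: float = 40.0
    wing_arm_mm: float = 5.840881
    angle_scale_deg_per_gmm: float = 10.576667
    baseline_moment_gmm: float = 0.460448
    sigma_individual_deg: float = 0.45
    sigma_meas_deg: float = 2.3
    cutoff_deg: float = 30.0

    def __post_init__(self) -> None:
        nonneg = {
            "straw_mass_g": self.straw_mass_g,
            "straw_length_mm": self.straw_length_mm,
            "full_elongation_mm": self.full_elongation_mm,
            "wing_mass_g": self.wing_mass_g,
            "tail_arm_mm": self.tail_arm_mm,
            "wing_arm_mm": self.wing_arm_mm,
            "sigma_individual_deg": self.sigma_individual_deg,
            "sigma_meas_deg": self.sigma_meas_deg,
        }
        for name, value in nonneg.items():
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be finite and >= 0")
        if not self.cutoff_deg > 0:
            raise ValueError("cutoff_deg must be > 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the shortening experiment (defaults match the study)."""

    n_individuals: int = 4
    treatments: tuple[float, ...] = (0.0, -20.0, -40.0, -60.0, -80.0)
    replicates: int = 2

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.replicates < 1 or not self.treatments:
            raise ValueError("design must have >=1 individual, treatment and replicate")
        if any(t > 0 for t in self.treatments):
            raise ValueError("treatments are shortenings and must be <= 0 mm")


def _effective_tail_mm(
    params: ToyPhysicalParams, strategy: ToyStrategy, manipulation_mm: float
) -> float:
    if manipulation_mm > 0:
        raise ValueError("manipulation_mm is a shortening and must be <= 0")
    remaining = strategy.tail_elongation_mm + manipulation_mm
    if remaining < 0:
        warnings.warn(
            "manipulation removes more tail than present; clamped to the "
            "bare ancestral tail",
            stacklevel=3,
        )
        remaining = 0.0
    return remaining


def net_moment(
    params: ToyPhysicalParams, strategy: ToyStrategy, manipulation_mm: float = 0.0
) -> float:
    """Signed net moment (g*mm): tail-heavy positive, wing-heavy negative."""
    remaining = _effective_tail_mm(params, strategy, manipulation_mm)
    tail_mass = params.straw_mass_g * remaining / params.straw_length_mm
    moment = tail_mass * params.tail_arm_mm
    if strategy.wings:
        moment -= 2.0 * params.wing_mass_g * params.wing_arm_mm
    return moment


def tilt_angle(
    params: ToyPhysicalParams,
    strategy: ToyStrategy,
    manipulation_mm: float = 0.0,
    individual_effect_deg: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Absolute tilt (degrees from horizontal), clipped at 90.

    With ``rng`` given, one Gaussian photo-noise draw (sd
    ``sigma_meas_deg``) is added before taking the absolute value; without
    it the tilt is deterministic.
    """
    moment = net_moment(params, strategy, manipulation_mm)
    tilt = (
        params.angle_scale_deg_per_gmm * (moment + params.baseline_moment_gmm)
        + individual_effect_deg
    )
    if rng is not None:
        tilt += rng.normal(0.0, params.sigma_meas_deg)
    return min(abs(tilt), 90.0)


def tilt_model(params: ToyPhysicalParams):
    """Deterministic signed-tilt function of a morph, for the ESS game."""

    def tilt(strategy: ToyStrategy) -> float:
        moment = net_moment(params, strategy, 0.0)
        return params.angle_scale_deg_per_gmm * (
            moment + params.baseline_moment_gmm
        )

    return tilt


def calibrate_generator(
    anchor_means: Mapping[str, float] | None = None,
    base: ToyPhysicalParams | None = None,
    rel_tol: float = 0.05,
) -> ToyPhysicalParams:
    """Fit (angle_scale, wing_arm, baseline_moment) to the anchor means.

    The three noise-free anchor conditions are linear in the unknowns and
    triangular, so the least-squares problem has an exact solution:

    * ancestral (no tail, no wings):  a * m0 = ancestral
    * wingless 30 mm tail:            a * (T30 + m0) = wingless_30mm
    * full 110 mm tail with wings:    a * (T110 - Mw + m0) = ess_full

    with a = angle_scale, m0 = baseline moment, Mw = wing moment and
    T_L the tail moment at L mm.  Raises `CalibrationError` if the anchors
    are degenerate (no tilt gain) or any fitted mean misses its anchor by
    more than ``rel_tol`` relative error.
    """
    anchors = dict(DEFAULT_ANCHORS if anchor_means is None else anchor_means)
    missing = {"ancestral", "ess_full", "wingless_30mm"} - set(anchors)
    if missing:
        raise CalibrationError(f"missing anchors: {sorted(missing)}")
    if any(not (math.isfinite(v) and v > 0) for v in anchors.values()):
        raise CalibrationError("anchor means must be finite and positive")
    base = base if base is not None else ToyPhysicalParams()

    density = base.straw_mass_g / base.straw_length_mm
    t30 = density * 30.0 * base.tail_arm_mm
    t_full = density * base.full_elongation_mm * base.tail_arm_mm

    # a*m0 = ancestral and a*(t30 + m0) = wingless_30mm => a*t30 = difference
    gain = anchors["wingless_30mm"] - anchors["ancestral"]
    if gain <= 0 or t30 <= 0:
        raise CalibrationError(
            "anchors give no tilt gain from tail mass (wingless_30mm must "
            "exceed ancestral); cannot calibrate angle_scale"
        )
    angle_scale = gain / t30
    baseline_moment = anchors["ancestral"] / angle_scale
    # a*(t_full - 2*wing_mass*wing_arm + m0) = ess_full
    wing_moment = t_full + baseline_moment - anchors["ess_full"] / angle_scale
    wing_arm = wing_moment / (2.0 * base.wing_mass_g)
    if wing_arm < 0:
        raise CalibrationError(
            "ess_full anchor exceeds the uncompensated full-tail tilt; "
            "wings would need a negative arm"
        )

    fitted = replace(
        base,
        angle_scale_deg_per_gmm=angle_scale,
        baseline_moment_gmm=baseline_moment,
        wing_arm_mm=wing_arm,
    )
    ancestral = ToyStrategy(0.0, wings=False)
    ess = ToyStrategy(base.full_elongation_mm, wings=True)
    wingless30 = ToyStrategy(30.0, wings=False)
    achieved = {
        "ancestral": tilt_angle(fitted, ancestral),
        "ess_full": tilt_angle(fitted, ess),
        "wingless_30mm": tilt_angle(fitted, wingless30),
    }
    residuals = {
        name: (achieved[name] - anchors[name]) / anchors[name]
        for name in anchors
    }
    if any(abs(res) > rel_tol for res in residuals.values()):
        raise CalibrationError(
            f"calibration misses anchors beyond {rel_tol:.0%}: {residuals}"
        )
    return fitted


def default_params() -> ToyPhysicalParams:
    """Parameters calibrated to the default anchor means."""
    return calibrate_generator(DEFAULT_ANCHORS)


def generate_experiment(
    params: ToyPhysicalParams,
    design: ExperimentDesign | None = None,
    seed: int | np.random.SeedSequence | None = None,
    strategy: ToyStrategy | None = None,
) -> pd.DataFrame:
    """Simulate the shortening experiment as a long-format table.

    One individual baseline effect ~ N(0, sigma_individual) per toy, one
    photo noise term ~ N(0, sigma_meas) per record.  The same seed always
    yields the identical table.  Columns:
    ``individual_id, treatment_mm, replicate, angle_deg``.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    design = design if design is not None else ExperimentDesign()
    if strategy is None:
        strategy = ToyStrategy(params.full_elongation_mm, wings=True)
    rng = np.random.default_rng(seed)
    individual_effects = rng.normal(
        0.0, params.sigma_individual_deg, size=design.n_individuals
    )
    records = []
    for i in range(design.n_individuals):
        ind_id = f"toy{i + 1}"
        for treatment in design.treatments:
            for rep in range(1, design.replicates + 1):
                angle = tilt_angle(
                    params,
                    strategy,
                    manipulation_mm=treatment,
                    individual_effect_deg=individual_effects[i],
                    rng=rng,
                )
                records.append((ind_id, float(treatment), rep, angle))
    return pd.DataFrame(records, columns=EXPERIMENT_COLUMNS)
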