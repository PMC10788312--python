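"""Replicate averaging, ANOVA repeatability, and design-matrix assembly.

Mirrors the measurement-reduction stage of a shortening experiment: the two
photos per (individual, treatment) cell are averaged, their agreement is
summarized as the intraclass correlation from a one-way ANOVA, and the
averaged table is turned into response/design matrices for the mixed model
(linear + quadratic terms of a scaled manipulation predictor, individual as
the grouping factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .toy import EXPERIMENT_COLUMNS

__all__ = [
    "MissingDataError",
    "UndefinedRepeatabilityError",
    "RepeatabilityResult",
    "DesignMatrices",
    "average_replicates",
    "repeatability",
    "repeatability_from_f",
    "build_design",
    "FIXED_EFFECT_NAMES",
]

FIXED_EFFECT_NAMES = ("intercept", "linear", "quadratic")


class MissingDataError(ValueError):
    """A cell of the individual x treatment design has no measurements."""


class UndefinedRepeatabilityError(ValueError):
    """All groups are singletons; within-group variance is undefined."""


def _check_experiment_table(table: pd.DataFrame) -> None:
    missing_cols = set(EXPERIMENT_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"table is missing columns: {sorted(missing_cols)}")
    if table.empty:
        raise ValueError("table is empty")
    if (table["angle_deg"] < 0).any():
        raise ValueError("angle_deg must be >= 0")


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean angle per (individual, treatment) cell.

    Every individual must have been measured at every treatment appearing
    in the table; a missing cell raises `MissingDataError` rather than
    silently shrinking the design.
    """
    _check_experiment_table(table)
    cells = (
        table.groupby(["individual_id", "treatment_mm"], sort=True)["angle_deg"]
        .mean()
        .reset_index()
        .rename(columns={"angle_deg": "mean_angle_deg"})
    )
    individuals = table["individual_id"].unique()
    treatments = table["treatment_mm"].unique()
    expected = len(individuals) * len(treatments)
    if len(cells) != expected:
        have = set(zip(cells["individual_id"], cells["treatment_mm"]))
        missing = [
            (ind, t)
            for ind in individuals
            for t in treatments
            if (ind, t) not in have
        ]
        raise MissingDataError(f"missing (individual, treatment) cells: {missing}")
    return cells


@dataclass(frozen=True)
class RepeatabilityResult:
    """One-way ANOVA intraclass correlation and its ingredients."""

    r: float
    F: float
    df_between: int
    df_within: int
    n0: float
    ms_between: float
    ms_within: float


def repeatability_from_f(F: float, n0: float) -> float:
    """Intraclass correlation from the ANOVA F ratio at common group size n0.

    For balanced groups, r = (F - 1) / (F - 1 + n0).
    """
    return (F - 1.0) / (F - 1.0 + n0)


def repeatability(
    table: pd.DataFrame, groups: str = "cell"
) -> RepeatabilityResult:
    """Repeatability of replicate measurements by one-way ANOVA.

    Groups default to the (individual, treatment) cells, so the statistic
    measures photo-to-photo agreement within a cell; ``groups="individual"``
    pools treatments instead.  Variance components follow the one-way ANOVA
    estimator: s2_A = (MS_A - MS_W) / n0 with n0 the average group size
    correction for unbalanced data, and r = s2_A / (s2_A + MS_W).
    """
    _check_experiment_table(table)
    if groups == "cell":
        labels = list(zip(table["individual_id"], table["treatment_mm"]))
    elif groups == "individual":
        labels = list(table["individual_id"])
    else:
        raise ValueError("groups must be 'cell' or 'individual'")
    y = table["angle_deg"].to_numpy(dtype=float)
    frame = pd.DataFrame({"y": y, "g": pd.Series(labels).astype(str)})
    sizes = frame.groupby("g")["y"].size().to_numpy(dtype=float)
    k = len(sizes)
    n_total = float(len(frame))
    if k < 2:
        raise ValueError("need >= 2 groups for the ANOVA")
    if (sizes <= 1).all():
        raise UndefinedRepeatabilityError(
            "all groups have a single measurement; within-group variance "
            "is undefined"
        )
    grand = y.mean()
    means = frame.groupby("g")["y"].mean().to_numpy(dtype=float)
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(
        ((frame["y"] - frame.groupby("g")["y"].transform("mean")) ** 2).sum()
    )
    df_between = k - 1
    df_within = int(n_total) - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    n0 = (n_total - np.sum(sizes**2) / n_total) / (k - 1)
    if ms_within == 0.0:
        # replicates agree exactly: all variance is between groups
        return RepeatabilityResult(
            r=1.0,
            F=np.inf,
            df_between=df_between,
            df_within=df_within,
            n0=n0,
            ms_between=ms_between,
            ms_within=0.0,
        )
    s2_between = (ms_between - ms_within) / n0
    r = s2_between / (s2_between + ms_within)
    return RepeatabilityResult(
        r=float(r),
        F=float(ms_between / ms_within),
        df_between=df_between,
        df_within=df_within,
        n0=float(n0),
        ms_between=float(ms_between),
        ms_within=float(ms_within),
    )


@dataclass(frozen=True)
class DesignMatrices:
    """Response, fixed-effect matrix and grouping labels for the LMM."""

    y: np.ndarray
    X: np.ndarray
    groups: np.ndarray
    predictor: np.ndarray
    scaling: str
    center: float
    scale: float

    @property
    def names(self) -> tuple[str, ...]:
        return FIXED_EFFECT_NAMES

    def predictor_range(self) -> tuple[float, float]:
        return float(self.predictor.min()), float(self.predictor.max())


def build_design(averaged: pd.DataFrame, scaling: str = "zscore") -> DesignMatrices:
    """Assemble y, X = [1, z, z^2] and group labels from the averaged table.

    ``scaling`` controls the manipulation predictor z:

    * ``zscore`` (default): center and scale by the mean and sd (ddof=1) of
      the distinct treatment levels, so the design points -- not the
      replication -- define the scale; the default five levels map to
      {+-1.2649, +-0.6325, 0}.
    * ``center``: subtract the mean level only.
    * ``raw``: use treatment_mm unchanged.
    """
    required = {"individual_id", "treatment_mm", "mean_angle_deg"}
    missing = required - set(averaged.columns)
    if missing:
        raise ValueError(f"averaged table missing columns: {sorted(missing)}")
    levels = np.unique(averaged["treatment_mm"].to_numpy(dtype=float))
    if len(levels) < 3:
        raise ValueError(
            "need >= 3 distinct treatments for an identifiable quadratic"
        )
    center = float(levels.mean())
    if scaling == "zscore":
        scale = float(levels.std(ddof=1))
    elif scaling == "center":
        scale = 1.0
    elif scaling == "raw":
        center, scale = 0.0, 1.0
    else:
        raise ValueError("scaling must be 'zscore', 'center' or 'raw'")
    t = averaged["treatment_mm"].to_numpy(dtype=float)
    z = (t - center) / scale
    X = np.column_stack([np.ones_like(z), z, z**2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrices(
        y=averaged["mean_angle_deg"].to_numpy(dtype=float),
        X=X,
        groups=averaged["individual_id"].to_numpy(),
        predictor=z,
        scaling=scaling,
        center=center,
        scale=scale,
    )
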