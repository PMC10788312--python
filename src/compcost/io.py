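"""CSV / YAML / JSON input-output for the experiment pipeline.

The experiment CSV dialect is comma-separated UTF-8 with the header
``individual_id,treatment_mm,replicate,angle_deg``; treatments are signed
mm (shortenings are negative), angles in degrees.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .surfaces import ConditionalCostCurve, QuadraticPerformanceSurface
from .toy import EXPERIMENT_COLUMNS

__all__ = [
    "ExperimentCSVError",
    "read_experiment_csv",
    "write_experiment_csv",
    "read_averaged_csv",
    "write_averaged_csv",
    "cost_curve_frame",
    "write_cost_curve_csv",
    "load_surface",
    "dump_surface",
    "write_json_report",
]


class ExperimentCSVError(ValueError):
    """A malformed experiment CSV (bad header, row, or duplicate record)."""


def read_experiment_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format experiment table.

    Errors name the offending CSV line (1-based, counting the header).
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(table.columns) != EXPERIMENT_COLUMNS:
        raise ExperimentCSVError(
            f"{path}: header must be {','.join(EXPERIMENT_COLUMNS)}, "
            f"got {','.join(table.columns)}"
        )
    parsed = table.copy()
    for column in ("treatment_mm", "angle_deg"):
        values = pd.to_numeric(table[column], errors="coerce")
        bad = values.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ExperimentCSVError(
                f"{path}: non-numeric {column} at line {line}: "
                f"{table[column][bad.idxmax()]!r}"
            )
        parsed[column] = values.astype(float)
    replicate = pd.to_numeric(table["replicate"], errors="coerce")
    bad = replicate.isna() | (replicate != replicate.round())
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ExperimentCSVError(f"{path}: non-integer replicate at line {line}")
    parsed["replicate"] = replicate.astype(int)
    if (parsed["angle_deg"] < 0).any():
        line = int((parsed["angle_deg"] < 0).idxmax()) + 2
        raise ExperimentCSVError(f"{path}: negative angle at line {line}")
    keys = ["individual_id", "treatment_mm", "replicate"]
    duplicated = parsed.duplicated(subset=keys)
    if duplicated.any():
        line = int(duplicated.idxmax()) + 2
        raise ExperimentCSVError(
            f"{path}: duplicate (individual, treatment, replicate) at line {line}"
        )
    return parsed


def write_experiment_csv(table: pd.DataFrame, path: str | Path) -> None:
    table = table[EXPERIMENT_COLUMNS]
    table.to_csv(path, index=False, float_format="%.6g")


def read_averaged_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = ["individual_id", "treatment_mm", "mean_angle_deg"]
    if list(table.columns) != required:
        raise ExperimentCSVError(
            f"{path}: header must be {','.join(required)}"
        )
    return table


def write_averaged_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.6g")


def cost_curve_frame(
    curve: ConditionalCostCurve, x1_values: np.ndarray
) -> pd.DataFrame:
    """Tabulate a conditional curve as (x1, performance, cost).

    Cost is the curve's best performance minus the performance at x1.
    """
    x1 = np.asarray(x1_values, dtype=float)
    performance = curve.evaluate(x1)
    best = curve.evaluate(curve.peak_x1)
    return pd.DataFrame(
        {"x1": x1, "performance": performance, "cost": best - performance}
    )


def write_cost_curve_csv(
    curve: ConditionalCostCurve, x1_values: np.ndarray, path: str | Path
) -> None:
    cost_curve_frame(curve, x1_values).to_csv(path, index=False)


def load_surface(path: str | Path) -> QuadraticPerformanceSurface:
    """Read surface coefficients from a flat YAML/JSON mapping."""
    text = Path(path).read_text()
    entries = yaml.safe_load(text)
    if not isinstance(entries, dict):
        raise ValueError(f"{path}: expected a mapping of coefficients")
    return QuadraticPerformanceSurface.from_dict(entries)


def dump_surface(surface: QuadraticPerformanceSurface, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(surface.to_dict(), sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else repr(obj)
    return obj


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")
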