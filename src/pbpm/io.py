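"""File formats and configuration.

Curves travel as delimited text (CSV) with columns
``subject_id, time_min, concentration[, weight]``; parameters and reports
as JSON with sorted keys and floats at 12 significant digits, so that
identical runs produce byte-identical files; configuration as YAML with
unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aif_core import SamplingCurve

__all__ = ["ProjectConfig", "read_cohort", "write_cohort", "write_results",
           "read_results", "SCHEMA_VERSION"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

CURVE_COLUMNS = ("subject_id", "time_min", "concentration")


@dataclass
class ProjectConfig:
    """Validated run configuration (YAML-loadable)."""

    tracer: str = "fdg"
    J: int | None = None
    delta_grid_points: int = 21
    delta_window_min: tuple[float, float] = (-1.0, 1.0)
    lambda_grid_points: int = 15
    lambda_range_log10: tuple[float, float] = (-4.0, 3.0)
    elbow_threshold: float = 0.05
    ordering_constraint: bool = False
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProjectConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("delta_window_min", "lambda_range_log10"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if cfg.delta_grid_points < 1 or cfg.lambda_grid_points < 1:
            raise ValueError("grid sizes must be positive")
        return cfg

    def delta_grid(self) -> np.ndarray:
        lo, hi = self.delta_window_min
        return np.linspace(lo, hi, self.delta_grid_points)

    def lambda_grid(self) -> np.ndarray:
        lo, hi = self.lambda_range_log10
        return np.concatenate([[0.0], np.logspace(lo, hi, self.lambda_grid_points)])

    def digest(self) -> str:
        """Stable hash of the configuration, for run logging."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_cohort(path: str | Path, injection_duration: float = 1.0,
                tracer: str = "") -> list[SamplingCurve]:
    """Read sampling curves grouped by ``subject_id`` from a CSV file.

    A missing ``weight`` column defaults to 1; an ``injection_duration``
    column, if present, overrides the argument per subject.  Malformed
    subjects raise with the subject named.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty cohort file")
        return []
    if df.empty:
        warnings.warn(f"{path}: empty cohort file")
        return []
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    bad = df[~np.isfinite(df["time_min"]) | ~np.isfinite(df["concentration"])]
    if len(bad):
        lines = (bad.index + 2).tolist()  # header + 1-based
        raise ValueError(f"{path}: malformed rows at line(s) {lines}")
    curves = []
    for sid, group in df.groupby("subject_id", sort=False):
        group = group.sort_values("time_min", kind="stable")
        dur = injection_duration
        if "injection_duration" in group.columns:
            dur = float(group["injection_duration"].iloc[0])
        curves.append(SamplingCurve(subject_id=str(sid),
                                    times=group["time_min"].to_numpy(),
                                    concentrations=group["concentration"].to_numpy(),
                                    weights=group["weight"].to_numpy(),
                                    injection_duration=dur, tracer=tracer))
    return curves


def write_cohort(curves: list[SamplingCurve], path: str | Path) -> None:
    """Write sampling curves to the cohort CSV format."""
    frames = [pd.DataFrame({"subject_id": c.subject_id, "time_min": c.times,
                            "concentration": c.concentrations, "weight": c.weights,
                            "injection_duration": c.injection_duration})
              for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.12g")


def _jsonable(obj):
    """Convert nested dataclasses / numpy objects to plain JSON types with
    floats rounded to 12 significant digits (reproducible diffs)."""
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.12g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (bool, str)) or obj is None:
        return obj
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def write_results(objects: dict, path: str | Path) -> None:
    """Serialize a result dictionary to JSON (schema-versioned, sorted keys,
    12-significant-digit floats)."""
    payload = {"schema_version": SCHEMA_VERSION, **_jsonable(objects)}
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def read_results(path: str | Path) -> dict:
    """Read back a JSON results file written by :func:`write_results`."""
    return json.loads(Path(path).read_text())
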