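"""Table schemas, deterministic CSV I/O, and the run configuration.

CSV with fixed, bit-exact headers is the interchange format; frame indices
are 0-based, times are seconds from session start, and the wall-clock
anchor lives in the config. JSON carries reports and fitted models.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .geometry import CageGeometry, Calibration
from .metrics import MetricConfig
from .simulate import SimConfig
from .tracker import TrackerConfig

SCHEMAS: dict[str, list[str]] = {
    "detections": [
        "frame", "body_x1", "body_y1", "body_x2", "body_y2",
        "head_x1", "head_y1", "head_x2", "head_y2",
        "score", "is_bundle", "member_count",
    ],
    "tags": ["frame", "tag_id", "x", "y", "score"],
    "trajectory": [
        "frame", "mouse_id", "x_cm", "y_cm", "head_x_cm", "head_y_cm",
        "head_dir_deg", "area_px", "status",
    ],
    "truth": ["frame", "mouse_id", "x_cm", "y_cm", "head_dir_deg", "state",
              "area_px"],
    "annotations": ["frame", "mouse_id", "behavior"],
    "metrics": ["mouse_id", "bin_id", "phase", "metric", "value"],
}

_INT_COLS = {"frame", "mouse_id", "tag_id"}


class SchemaError(ValueError):
    pass


def _check_schema(columns, schema_name: str) -> list[str]:
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    want = SCHEMAS[schema_name]
    missing = [c for c in want if c not in columns]
    extra = [c for c in columns if c not in want]
    if missing or extra:
        raise SchemaError(
            f"{schema_name}: missing columns {missing}, unexpected columns {extra}"
        )
    return want


def read_tables(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema; row order preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    want = _check_schema(list(df.columns), schema_name)
    df = df[want]
    for c in want:
        if c in _INT_COLS:
            bad = df[c].isna()
            if bad.any():
                raise SchemaError(
                    f"{schema_name}.{c}: unparseable value at row "
                    f"{int(np.nonzero(bad.to_numpy())[0][0])}"
                )
            try:
                df[c] = df[c].astype(np.int64)
            except (ValueError, TypeError) as e:
                raise SchemaError(f"{schema_name}.{c}: {e}") from e
    return df


def _validate_invariants(df: pd.DataFrame, schema_name: str) -> None:
    if schema_name in ("trajectory", "truth", "annotations"):
        dup = df.duplicated(subset=["frame", "mouse_id"])
        if dup.any():
            raise SchemaError(
                f"{schema_name}: duplicate (frame, mouse_id) at row "
                f"{int(np.nonzero(dup.to_numpy())[0][0])}"
            )
    if schema_name in ("detections", "tags") and "score" in df.columns:
        s = df["score"].to_numpy(dtype=float)
        if np.nanmin(s, initial=0.0) < 0 or np.nanmax(s, initial=0.0) > 1:
            raise SchemaError(f"{schema_name}: score outside [0, 1]")


def write_tables(table: pd.DataFrame, path, schema_name: str) -> None:
    """Write a validated table with deterministic column order and float
    formatting (identical input yields identical bytes)."""
    want = _check_schema(list(table.columns), schema_name)
    df = table[want]
    _validate_invariants(df, schema_name)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")


class RunConfig(BaseModel):
    """Resolved configuration for a full pipeline run."""

    model_config = ConfigDict(extra="forbid")

    geom: CageGeometry = Field(default_factory=CageGeometry)
    cal: Calibration = Field(default_factory=Calibration)
    tracker: TrackerConfig = Field(default_factory=TrackerConfig)
    metrics: MetricConfig = Field(default_factory=MetricConfig)
    sim: SimConfig | None = None
    roster_ids: list[int] = Field(default_factory=lambda: [1, 2, 3, 4])
    fps: float = 10.0
    session_start_s: float = 8 * 3600.0
    seed: int = 0
    log_level: str = "INFO"


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run config; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
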