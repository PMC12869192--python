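"""Cage coordinate model: pixel/centimeter calibration and zone geometry.

The floor is a continuous-cm rectangle with the origin at the front-left
corner and y increasing toward the back wall. All zone boundaries are
inclusive: a point exactly ``center_margin_cm`` from a wall counts as
center, a point exactly on a corner-square edge counts as corner.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: axis-aligned rectangle (x1, y1, x2, y2), x1 <= x2, y1 <= y2
Rect = tuple[float, float, float, float]

Wall = Literal["left", "right", "back", "front"]


class ConfigurationError(ValueError):
    """Raised when a calibration or geometry config is invalid."""


class Calibration(BaseModel):
    """Affine pixel<->centimeter mapping (axis-aligned, no lens model).

    ``origin_px`` is the pixel mapped to cm-coordinate (0, 0), i.e. the
    front-left floor corner in the image.
    """

    model_config = ConfigDict(extra="forbid")

    px_per_cm_x: float = Field(default=15.0, gt=0)
    px_per_cm_y: float = Field(default=15.0, gt=0)
    origin_px: tuple[float, float] = (80.0, 60.0)


def px_to_cm(point_px: np.ndarray, cal: Calibration) -> np.ndarray:
    """Map pixel coordinates to cm. Accepts a 2-vector or an (..., 2) array."""
    p = np.asarray(point_px, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite pixel coordinates")
    scale = np.array([cal.px_per_cm_x, cal.px_per_cm_y])
    return (p - np.asarray(cal.origin_px)) / scale


def cm_to_px(point_cm: np.ndarray, cal: Calibration) -> np.ndarray:
    """Inverse of :func:`px_to_cm`."""
    p = np.asarray(point_cm, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite cm coordinates")
    scale = np.array([cal.px_per_cm_x, cal.px_per_cm_y])
    return p * scale + np.asarray(cal.origin_px)


def _rect_valid(r: Rect) -> bool:
    return r[0] <= r[2] and r[1] <= r[3]


class CageGeometry(BaseModel):
    """Floor footprint, zone margins and fixture regions of interest (cm).

    Defaults describe an Allentown Jag75-like 32 x 18 cm floor with the food
    hopper and water spout on the front wall and an enrichment tube in the
    back-left quadrant. The hopper wall is excluded from the rearing wall
    bands (rears are scored against the three non-hopper walls only).
    """

    model_config = ConfigDict(extra="forbid")

    floor_width_cm: float = Field(default=32.0, gt=0)
    floor_depth_cm: float = Field(default=18.0, gt=0)
    center_margin_cm: float = Field(default=2.0, gt=0)
    corner_side_cm: float = Field(default=3.0, gt=0)
    wall_band_cm: float = Field(default=2.5, gt=0)
    hopper_roi: Rect = (10.0, 0.0, 22.0, 2.5)
    hopper_top_roi: Rect = (10.0, 0.0, 22.0, 1.0)
    spout_roi: Rect = (25.0, 0.0, 29.0, 2.0)
    tube_roi: Rect = (4.0, 10.0, 10.0, 14.0)
    tube_halo_cm: float = Field(default=1.0, ge=0)
    front_half: bool = True  # front = y <= floor_depth_cm / 2
    hopper_wall: Wall = "front"

    @model_validator(mode="after")
    def _check(self) -> "CageGeometry":
        w, d = self.floor_width_cm, self.floor_depth_cm
        if self.center_margin_cm >= min(w, d) / 2:
            raise ConfigurationError(
                "center_margin_cm must be < min(floor_width_cm, floor_depth_cm)/2"
            )
        for name in ("hopper_roi", "hopper_top_roi", "spout_roi", "tube_roi"):
            r = getattr(self, name)
            if not _rect_valid(r):
                raise ConfigurationError(f"{name} is not a valid rectangle: {r}")
            if r[0] < 0 or r[1] < 0 or r[2] > w or r[3] > d:
                raise ConfigurationError(f"{name} extends outside the floor: {r}")
        return self

    @property
    def rearing_walls(self) -> list[Wall]:
        return [w for w in ("left", "right", "back", "front") if w != self.hopper_wall]


class ZoneFlags(BaseModel):
    """Zone membership of one point; pure function of position and geometry."""

    model_config = ConfigDict(extra="forbid")

    center: bool
    front: bool
    corner: bool
    enrichment: bool
    wall_band_side: Literal["left", "right", "back", "front", "none"]


def _in_rect(x: np.ndarray, y: np.ndarray, r: Rect) -> np.ndarray:
    return (x >= r[0]) & (x <= r[2]) & (y >= r[1]) & (y <= r[3])


def classify_zones_arrays(points_cm: np.ndarray, geom: CageGeometry) -> dict:
    """Vectorized zone classification for an (N, 2) array of cm points.

    Points outside the floor are clamped onto it (with a warning). Returns a
    dict of arrays: boolean ``center``, ``front``, ``corner``, ``enrichment``
    and a string array ``wall_band_side``.
    """
    p = np.atleast_2d(np.asarray(points_cm, dtype=float))
    w, d = geom.floor_width_cm, geom.floor_depth_cm
    if np.any((p[:, 0] < 0) | (p[:, 0] > w) | (p[:, 1] < 0) | (p[:, 1] > d)):
        warnings.warn("points outside the floor rectangle were clamped", stacklevel=2)
    x = np.clip(p[:, 0], 0.0, w)
    y = np.clip(p[:, 1], 0.0, d)

    m = geom.center_margin_cm
    s = geom.corner_side_cm
    corner = ((x <= s) | (x >= w - s)) & ((y <= s) | (y >= d - s))
    center = (x >= m) & (x <= w - m) & (y >= m) & (y <= d - m) & ~corner
    front = y <= d / 2 if geom.front_half else y >= d / 2

    h = geom.tube_halo_cm
    t = geom.tube_roi
    enrichment = _in_rect(x, y, (t[0] - h, t[1] - h, t[2] + h, t[3] + h))

    # wall bands: distance to each of the three non-hopper walls; nearest wins
    dist = {"left": x, "right": w - x, "front": y, "back": d - y}
    band = np.full(len(x), "none", dtype=object)
    best = np.full(len(x), np.inf)
    for wall in geom.rearing_walls:
        dw = dist[wall]
        hit = (dw <= geom.wall_band_cm) & (dw < best)
        band[hit] = wall
        best = np.where(hit, dw, best)
    return {
        "center": center,
        "front": front,
        "corner": corner,
        "enrichment": enrichment,
        "wall_band_side": band,
    }


def classify_zones(point_cm, geom: CageGeometry) -> ZoneFlags:
    """Classify a single cm point into cage zones (see module docstring)."""
    z = classify_zones_arrays(np.asarray(point_cm, dtype=float).reshape(1, 2), geom)
    return ZoneFlags(
        center=bool(z["center"][0]),
        front=bool(z["front"][0]),
        corner=bool(z["corner"][0]),
        enrichment=bool(z["enrichment"][0]),
        wall_band_side=str(z["wall_band_side"][0]),
    )
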