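"""The 21 home-cage health and behavior metrics.

Everything is derived from an identity-resolved trajectory table: frame
kinematics (speed, acceleration, angular motion), an inactivity flag, zone
occupancy, and geometric behavior rules for eating, drinking, rearing,
climbing and aggression. Bouts are maximal runs of frame flags subject to
minimum durations; sleep is defined as continuous inactivity of at least
two minutes (a definition fixed by convention, not a tunable), and the
"max movement speed" is the mean of the top 1% of frame-wise speeds during
active periods, which suppresses single-frame spikes.

Metric panel names (9 categories, 21 metrics):
    activity/movement: acceleration_cm_s2, angular_motion_deg_s,
        avg_speed_cm_s, avg_awake_speed_cm_s, max_speed_cm_s, distance_cm
    social: aggression_events, aggression_time_pct, social_distance_cm
    occupancy: center_pct, front_pct, corner_pct, enrichment_pct
    climbing/rearing: climb_time_pct, climbing_events, rearing_events,
        rearing_time_pct
    consumption: drinking_pct, eating_pct
    sleep: sleep_bouts, sleep_time_pct
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .geometry import CageGeometry, classify_zones_arrays, _in_rect

#: definitional constants (paper-fixed, not tunable)
SLEEP_MIN_S = 120.0
TOP_SPEED_FRACTION = 0.01

METRIC_NAMES = [
    "acceleration_cm_s2", "angular_motion_deg_s", "avg_speed_cm_s",
    "avg_awake_speed_cm_s", "max_speed_cm_s", "distance_cm",
    "aggression_events", "aggression_time_pct", "social_distance_cm",
    "center_pct", "front_pct", "corner_pct", "enrichment_pct",
    "climb_time_pct", "climbing_events", "rearing_events", "rearing_time_pct",
    "drinking_pct", "eating_pct", "sleep_bouts", "sleep_time_pct",
]


class MetricConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fps: float = Field(default=10.0, gt=0)
    smooth_window_frames: int = Field(default=5, ge=1)
    inactivity_speed_cm_s: float = Field(default=0.5, gt=0)
    inactivity_smooth_s: float = Field(default=10.0, gt=0)
    sleep_min_s: float = 120.0
    top_fraction: float = 0.01
    aggr_proximity_cm: float = Field(default=5.0, gt=0)
    aggr_merge_gap_s: float = Field(default=5.0, gt=0)
    aggr_min_bout_s: float = Field(default=5.0, ge=0)
    aggr_chase_speed_cm_s: float = Field(default=8.0, gt=0)
    aggr_turn_deg_s: float = Field(default=180.0, gt=0)
    aggr_contact_cm: float = Field(default=3.0, gt=0)
    rear_area_ratio: float = Field(default=0.6, gt=0, le=1)
    rear_min_s: float = Field(default=0.5, gt=0)
    climb_min_s: float = Field(default=0.5, gt=0)
    dwell_min_s: float = Field(default=1.0, gt=0)
    head_cone_deg: float = Field(default=60.0, gt=0, le=180)
    light_period: tuple[str, str] = ("08:00", "20:00")

    @field_validator("sleep_min_s")
    @classmethod
    def _sleep_fixed(cls, v):
        if v != SLEEP_MIN_S:
            raise ValueError("sleep_min_s is fixed at 120 s by definition")
        return v

    @field_validator("top_fraction")
    @classmethod
    def _top_fixed(cls, v):
        if v != TOP_SPEED_FRACTION:
            raise ValueError("top_fraction is fixed at 0.01 by definition")
        return v


# ---------------------------------------------------------------------------
# run-length utilities


def flag_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end_exclusive) index pairs."""
    f = np.asarray(flags, dtype=bool)
    if f.size == 0:
        return []
    d = np.diff(f.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if f[0]:
        starts.insert(0, 0)
    if f[-1]:
        ends.append(len(f))
    return list(zip(starts, ends))


def filter_runs(flags: np.ndarray, min_frames: int) -> np.ndarray:
    """Zero out runs shorter than ``min_frames``."""
    out = np.zeros(len(flags), dtype=bool)
    for a, b in flag_runs(flags):
        if b - a >= min_frames:
            out[a:b] = True
    return out


def merge_runs(
    runs: list[tuple[int, int]], max_gap_frames: int
) -> list[tuple[int, int]]:
    """Merge runs separated by gaps of at most ``max_gap_frames``."""
    if not runs:
        return []
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] <= max_gap_frames:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [tuple(r) for r in merged]


# ---------------------------------------------------------------------------
# trajectory preparation and frame features


def _pivot(traj: pd.DataFrame, col: str) -> np.ndarray:
    t = traj.sort_values(["frame", "mouse_id"], kind="stable")
    n = t["mouse_id"].nunique()
    v = t[col].to_numpy(dtype=float) if col != "status" else t[col].to_numpy()
    return v.reshape(-1, n)


def smooth_trajectories(traj: pd.DataFrame, config: MetricConfig) -> pd.DataFrame:
    """Centered moving-median smoothing of body (and head) coordinates per
    mouse; edges use shrunken windows; a window of 1 is the identity."""
    w = config.smooth_window_frames
    out = traj.sort_values(["mouse_id", "frame"], kind="stable").copy()
    if w > 1:
        cols = [c for c in ("x_cm", "y_cm", "head_x_cm", "head_y_cm")
                if c in out.columns]
        g = out.groupby("mouse_id", sort=False)
        for c in cols:
            out[c] = g[c].transform(
                lambda s: s.rolling(w, center=True, min_periods=1).median()
            )
    return out.sort_values(["frame", "mouse_id"], kind="stable").reset_index(drop=True)


@dataclass
class FrameFeatures:
    """Per-(frame, mouse) arrays of shape (n_frames, n_mice)."""

    mouse_ids: np.ndarray
    fps: float
    x: np.ndarray
    y: np.ndarray
    head_x: np.ndarray
    head_y: np.ndarray
    area: np.ndarray
    speed: np.ndarray
    accel: np.ndarray
    angular_vel: np.ndarray
    move_dir_deg: np.ndarray
    moving: np.ndarray
    inactive: np.ndarray
    center: np.ndarray
    front: np.ndarray
    corner: np.ndarray
    enrichment: np.ndarray
    wall_band: np.ndarray
    eating: np.ndarray
    drinking: np.ndarray
    rearing: np.ndarray
    climbing: np.ndarray
    aggression: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]


def _kinematics(x, y, fps, config):
    n_frames, n = x.shape
    dx = np.diff(x, axis=0, prepend=x[:1])
    dy = np.diff(y, axis=0, prepend=y[:1])
    speed = np.hypot(dx, dy) * fps
    speed[0] = 0.0
    accel = np.diff(speed, axis=0, prepend=speed[:1]) * fps
    accel[0] = 0.0
    theta = np.degrees(np.arctan2(dy, dx))
    disp = np.hypot(dx, dy)
    dth = np.diff(theta, axis=0, prepend=theta[:1])
    dth = (dth + 180.0) % 360.0 - 180.0
    angular = dth * fps
    # heading is undefined below the movement threshold (sub-threshold
    # displacements are localization noise, not turning)
    thr_disp = config.inactivity_speed_cm_s / fps
    bad = (disp <= thr_disp) | (np.roll(disp, 1, axis=0) <= thr_disp)
    bad[:2] = True
    angular[bad] = 0.0
    theta[disp <= thr_disp] = np.nan
    moving = speed > config.inactivity_speed_cm_s
    w = max(1, int(round(config.inactivity_smooth_s * fps)))
    frac = (
        pd.DataFrame(moving.astype(float))
        .rolling(w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    # the windowed rule alone defines inactivity: isolated single-frame
    # movement (e.g. a jostle from a cage mate) must not split a rest bout
    inactive = frac < 0.1
    # the centered window delays onset/offset by ~half its width; extend
    # inactivity over each contiguous still period whose core passes the
    # windowed test, so bout boundaries land on the actual stillness edges
    for j in range(n):
        still = ~moving[:, j]
        d = np.diff(still.astype(np.int8))
        starts = list(np.nonzero(d == 1)[0] + 1)
        ends = list(np.nonzero(d == -1)[0] + 1)
        if still[0]:
            starts.insert(0, 0)
        if still[-1]:
            ends.append(n_frames)
        for a, b in zip(starts, ends):
            if inactive[a:b, j].any():
                inactive[a:b, j] = True
    return speed, accel, angular, theta, moving, inactive


def _facing(bx, by, hdir_deg, target, cone_deg):
    """True where the head direction is within ``cone_deg`` of the direction
    from the body to ``target``."""
    tx, ty = target
    want = np.degrees(np.arctan2(ty - by, tx - bx))
    d = (hdir_deg - want + 180.0) % 360.0 - 180.0
    return np.abs(d) <= cone_deg


def compute_frame_features(
    traj: pd.DataFrame, geom: CageGeometry, config: MetricConfig
) -> FrameFeatures:
    """Kinematics, zone flags and behavior flags from a smoothed trajectory.

    Eat/drink/rear/climb flags are already filtered to their minimum dwell
    durations; the aggression flag is the raw frame-level pair rule (bout
    merging happens in :func:`aggression_metrics`).
    """
    fps = config.fps
    ids = np.sort(traj["mouse_id"].unique())
    n = len(ids)
    x, y = _pivot(traj, "x_cm"), _pivot(traj, "y_cm")
    hx = _pivot(traj, "head_x_cm") if "head_x_cm" in traj.columns else np.full_like(x, np.nan)
    hy = _pivot(traj, "head_y_cm") if "head_y_cm" in traj.columns else np.full_like(x, np.nan)
    hd = _pivot(traj, "head_dir_deg") if "head_dir_deg" in traj.columns else np.full_like(x, np.nan)
    area = _pivot(traj, "area_px") if "area_px" in traj.columns else np.full_like(x, np.nan)
    n_frames = x.shape[0]

    speed, accel, angular, move_dir, moving, inactive = _kinematics(x, y, fps, config)

    z = classify_zones_arrays(np.stack([x.ravel(), y.ravel()], axis=1), geom)
    shape = (n_frames, n)
    center = z["center"].reshape(shape)
    front = z["front"].reshape(shape)
    corner = z["corner"].reshape(shape)
    enrichment = z["enrichment"].reshape(shape)
    wall_band = z["wall_band_side"].reshape(shape)

    # head direction: fall back to the body-to-head vector where absent
    vec_dir = np.degrees(np.arctan2(hy - y, hx - x))
    hdir = np.where(np.isfinite(hd), hd, vec_dir)

    # eating / drinking: head centroid inside the ROI, facing it, dwell-filtered
    head_ok = np.isfinite(hx) & np.isfinite(hy) & np.isfinite(hdir)
    hc = ((geom.hopper_roi[0] + geom.hopper_roi[2]) / 2,
          (geom.hopper_roi[1] + geom.hopper_roi[3]) / 2)
    sc = ((geom.spout_roi[0] + geom.spout_roi[2]) / 2,
          (geom.spout_roi[1] + geom.spout_roi[3]) / 2)
    in_hop = _in_rect(hx, hy, geom.hopper_roi) & head_ok
    in_spt = _in_rect(hx, hy, geom.spout_roi) & head_ok
    eat = in_hop & _facing(x, y, hdir, hc, config.head_cone_deg)
    drk = in_spt & _facing(x, y, hdir, sc, config.head_cone_deg)
    both = eat & drk  # nearer ROI wins
    if both.any():
        d_h = np.hypot(hx - hc[0], hy - hc[1])
        d_s = np.hypot(hx - sc[0], hy - sc[1])
        eat[both & (d_s < d_h)] = False
        drk[both & (d_h <= d_s)] = False
    dwell_f = max(1, int(round(config.dwell_min_s * fps)))
    for j in range(n):
        eat[:, j] = filter_runs(eat[:, j], dwell_f)
        drk[:, j] = filter_runs(drk[:, j], dwell_f)

    # rearing / climbing via body-area foreshortening
    med = np.nanmedian(area, axis=0)
    small = area < config.rear_area_ratio * med[None, :]
    in_tube = _in_rect(x, y, geom.tube_roi)
    climb = _in_rect(x, y, geom.hopper_top_roi) & small
    rear = (wall_band != "none") & small & ~in_tube & ~climb
    for j in range(n):
        climb[:, j] = filter_runs(climb[:, j], max(1, int(round(config.climb_min_s * fps))))
        rear[:, j] = filter_runs(rear[:, j], max(1, int(round(config.rear_min_s * fps))))

    # aggression frame rule: proximity + (directed chase or mutual turning
    # in contact); symmetric, flags both participants
    aggr = np.zeros(shape, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(x[:, i] - x[:, j], y[:, i] - y[:, j])
            close = d < config.aggr_proximity_cm
            if not close.any():
                continue
            chase_i = (speed[:, i] > config.aggr_chase_speed_cm_s) & _facing(
                x[:, i], y[:, i], move_dir[:, i], (x[:, j], y[:, j]),
                config.head_cone_deg,
            )
            chase_j = (speed[:, j] > config.aggr_chase_speed_cm_s) & _facing(
                x[:, j], y[:, j], move_dir[:, j], (x[:, i], y[:, i]),
                config.head_cone_deg,
            )
            turning = (
                (np.abs(angular[:, i]) > config.aggr_turn_deg_s)
                & (np.abs(angular[:, j]) > config.aggr_turn_deg_s)
                & (d < config.aggr_contact_cm)
            )
            hit = close & (chase_i | chase_j | turning)
            aggr[:, i] |= hit
            aggr[:, j] |= hit

    return FrameFeatures(
        mouse_ids=ids, fps=fps, x=x, y=y, head_x=hx, head_y=hy, area=area,
        speed=speed, accel=accel, angular_vel=angular, move_dir_deg=move_dir,
        moving=moving, inactive=inactive, center=center, front=front,
        corner=corner, enrichment=enrichment, wall_band=wall_band,
        eating=eat, drinking=drk, rearing=rear, climbing=climb, aggression=aggr,
    )


# ---------------------------------------------------------------------------
# per-bin metric functions (operate on one mouse column + a bin mask)


def summarize_movement(ff: FrameFeatures, j: int, mask: np.ndarray) -> dict:
    sp = ff.speed[mask, j]
    active = ~ff.inactive[mask, j]
    mv = ff.moving[mask, j]
    out = {
        "avg_speed_cm_s": float(np.mean(sp)) if len(sp) else np.nan,
        "distance_cm": float(np.sum(sp)) / ff.fps,
    }
    if active.any():
        sa = np.sort(sp[active])[::-1]
        k = max(1, int(np.floor(TOP_SPEED_FRACTION * active.sum())))
        out["avg_awake_speed_cm_s"] = float(np.mean(sp[active]))
        out["max_speed_cm_s"] = float(np.mean(sa[:k]))
    else:
        warnings.warn("no active frames in bin; awake/max speed undefined")
        out["avg_awake_speed_cm_s"] = np.nan
        out["max_speed_cm_s"] = np.nan
    out["acceleration_cm_s2"] = (
        float(np.mean(np.abs(ff.accel[mask, j][mv]))) if mv.any() else np.nan
    )
    out["angular_motion_deg_s"] = (
        float(np.mean(np.abs(ff.angular_vel[mask, j][mv]))) if mv.any() else np.nan
    )
    return out


def sleep_frame_flags(ff: FrameFeatures, j: int) -> tuple[np.ndarray, list]:
    """Sleep = maximal inactivity runs lasting >= 2 min; returns per-frame
    sleep flags and the qualifying runs."""
    min_f = int(round(SLEEP_MIN_S * ff.fps))
    runs = [r for r in flag_runs(ff.inactive[:, j]) if r[1] - r[0] >= min_f]
    flags = np.zeros(ff.n_frames, dtype=bool)
    for a, b in runs:
        flags[a:b] = True
    return flags, runs


def sleep_metrics(ff: FrameFeatures, j: int, mask: np.ndarray) -> dict:
    flags, runs = sleep_frame_flags(ff, j)
    nbin = int(mask.sum())
    return {
        "sleep_bouts": float(sum(1 for a, _ in runs if mask[a])),
        "sleep_time_pct": 100.0 * flags[mask].sum() / nbin if nbin else np.nan,
    }


def occupancy_metrics(ff: FrameFeatures, j: int, mask: np.ndarray) -> dict:
    nbin = int(mask.sum())
    if not nbin:
        return {k: np.nan for k in ("center_pct", "front_pct", "corner_pct",
                                    "enrichment_pct")}
    return {
        "center_pct": 100.0 * ff.center[mask, j].sum() / nbin,
        "front_pct": 100.0 * ff.front[mask, j].sum() / nbin,
        "corner_pct": 100.0 * ff.corner[mask, j].sum() / nbin,
        "enrichment_pct": 100.0 * ff.enrichment[mask, j].sum() / nbin,
    }


def consumption_metrics(ff: FrameFeatures, j: int, mask: np.ndarray) -> dict:
    nbin = int(mask.sum())
    if not np.isfinite(ff.head_x[:, j]).any():
        warnings.warn("no head coordinates; eating/drinking emitted as missing")
        return {"eating_pct": np.nan, "drinking_pct": np.nan}
    return {
        "eating_pct": 100.0 * ff.eating[mask, j].sum() / nbin if nbin else np.nan,
        "drinking_pct": 100.0 * ff.drinking[mask, j].sum() / nbin if nbin else np.nan,
    }


def _event_metrics(flags: np.ndarray, mask: np.ndarray, pct_name: str,
                   count_name: str) -> dict:
    nbin = int(mask.sum())
    runs = flag_runs(flags)
    return {
        count_name: float(sum(1 for a, _ in runs if mask[a])),
        pct_name: 100.0 * flags[mask].sum() / nbin if nbin else np.nan,
    }


def rearing_metrics(ff: FrameFeatures, j: int, mask: np.ndarray) -> dict:
    return _event_metrics(ff.rearing[:, j], mask, "rearing_time_pct",
                          "rearing_events")


def climbing_metrics(ff: FrameFeatures, j: int, mask: np.ndarray) -> dict:
    return _event_metrics(ff.climbing[:, j], mask, "climb_time_pct",
                          "climbing_events")


def aggression_bouts(ff: FrameFeatures, j: int, config: MetricConfig) -> list:
    """Merged aggression bouts (frame intervals) for one mouse: flagged
    intervals separated by gaps <= the merge gap are one bout; bouts shorter
    than ``aggr_min_bout_s`` are discarded as frame-level noise."""
    gap = int(round(config.aggr_merge_gap_s * ff.fps))
    min_f = int(round(config.aggr_min_bout_s * ff.fps))
    flags = ff.aggression[:, j]
    runs = merge_runs(flag_runs(flags), gap)
    # the minimum applies to genuinely flagged time, not the merged span:
    # sparse incidental flags strung together by the merge gap are noise
    return [r for r in runs if int(flags[r[0]:r[1]].sum()) >= max(1, min_f)]


def aggression_metrics(ff: FrameFeatures, j: int, mask: np.ndarray,
                       config: MetricConfig) -> dict:
    if len(ff.mouse_ids) < 2:
        return {"aggression_events": 0.0, "aggression_time_pct": 0.0}
    bouts = aggression_bouts(ff, j, config)
    flags = np.zeros(ff.n_frames, dtype=bool)
    for a, b in bouts:
        flags[a:b] = True
    nbin = int(mask.sum())
    return {
        "aggression_events": float(sum(1 for a, _ in bouts if mask[a])),
        "aggression_time_pct": 100.0 * flags[mask].sum() / nbin if nbin else np.nan,
    }


def social_distance(ff: FrameFeatures, j: int, mask: np.ndarray) -> dict:
    n = len(ff.mouse_ids)
    if n < 2:
        warnings.warn("single animal: social distance undefined")
        return {"social_distance_cm": np.nan}
    others = [k for k in range(n) if k != j]
    d = np.min(
        np.stack(
            [np.hypot(ff.x[:, j] - ff.x[:, k], ff.y[:, j] - ff.y[:, k])
             for k in others],
            axis=1,
        ),
        axis=1,
    )
    return {"social_distance_cm": float(np.mean(d[mask])) if mask.any() else np.nan}


# ---------------------------------------------------------------------------
# binning and panel assembly


def _parse_clock(s: str) -> float:
    h, m = s.split(":")
    return 3600.0 * int(h) + 60.0 * int(m)


def bin_masks(
    n_frames: int, fps: float, session_start_s: float, config: MetricConfig,
    bins=("session", "24h", "light", "dark"),
) -> list[tuple[str, str, np.ndarray]]:
    """(bin_id, phase, frame mask) triples for the requested bin kinds."""
    t = np.arange(n_frames) / fps
    clock = (session_start_s + t) % 86400.0
    lo, hi = (_parse_clock(p) for p in config.light_period)
    light = (clock >= lo) & (clock < hi)
    out = []
    if "session" in bins:
        out.append(("session", "all", np.ones(n_frames, dtype=bool)))
    if "24h" in bins:
        nday = int(np.ceil(n_frames / fps / 86400.0))
        if nday > 1:
            for k in range(nday):
                m = (t >= k * 86400.0) & (t < (k + 1) * 86400.0)
                out.append((f"day{k}", "all", m))
    if "light" in bins:
        out.append(("session", "light", light))
    if "dark" in bins:
        out.append(("session", "dark", ~light))
    return out


def aggregate_panel(
    traj: pd.DataFrame,
    geom: CageGeometry,
    config: MetricConfig,
    session_start_s: float = 8 * 3600.0,
    bins=("session", "24h", "light", "dark"),
) -> pd.DataFrame:
    """Smooth, featurize and aggregate the full 21-metric panel.

    Returns a tidy frame (mouse_id, bin_id, phase, metric, value); bins
    without data yield rows with missing values.
    """
    sm = smooth_trajectories(traj, config)
    ff = compute_frame_features(sm, geom, config)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for bin_id, phase, mask in bin_masks(
            ff.n_frames, config.fps, session_start_s, config, bins
        ):
            for j, mid in enumerate(ff.mouse_ids):
                vals: dict[str, float] = {}
                if mask.any():
                    vals.update(summarize_movement(ff, j, mask))
                    vals.update(sleep_metrics(ff, j, mask))
                    vals.update(occupancy_metrics(ff, j, mask))
                    vals.update(consumption_metrics(ff, j, mask))
                    vals.update(rearing_metrics(ff, j, mask))
                    vals.update(climbing_metrics(ff, j, mask))
                    vals.update(aggression_metrics(ff, j, mask, config))
                    vals.update(social_distance(ff, j, mask))
                for name in METRIC_NAMES:
                    rows.append(
                        (int(mid), bin_id, phase, name, vals.get(name, np.nan))
                    )
    return pd.DataFrame(rows, columns=["mouse_id", "bin_id", "phase", "metric",
                                       "value"])
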