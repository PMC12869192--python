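"""Agent-based simulator of group-housed mice under an overhead camera.

Produces ground-truth tracks, degraded per-frame detections (with contact
"bundles" and random misses), ear-tag sightings, and per-frame behavior
annotations, so the tracker, metrics engine and validation statistics can
all be exercised without any external video data.

Behavior dynamics are a semi-Markov state machine: each animal dwells in a
state for a uniformly sampled duration, then transitions according to
configurable next-state weights. Movement during locomotion is a reflected
correlated random walk; goal-directed states (eating, drinking, climbing,
rearing, tube use, sleeping) are preceded by a directed walk to the target
fixture, recorded as locomotion. Aggression is a coordinated chase between
two animals. The acquisition regime emulated is an overhead 640x480 px
camera at 10 frames/s over a 12 h light/dark cycle, with ear tags sighted
on average every few seconds during activity and invisible during sleep
and occlusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .geometry import CageGeometry, Calibration, ConfigurationError, cm_to_px


class BehaviorState(str, Enum):
    LOCOMOTE = "LOCOMOTE"
    REST_SLEEP = "REST_SLEEP"
    EAT = "EAT"
    DRINK = "DRINK"
    REAR = "REAR"
    CLIMB = "CLIMB"
    TUBE = "TUBE"
    AGGRESSION = "AGGRESSION"


STATES: list[str] = [s.value for s in BehaviorState]
_ACTIVE = [s for s in STATES if s != "REST_SLEEP"]

_DEFAULT_DWELL = {
    "LOCOMOTE": (5.0, 30.0),
    "REST_SLEEP": (150.0, 240.0),
    "EAT": (10.0, 60.0),
    "DRINK": (5.0, 20.0),
    "REAR": (2.0, 8.0),
    "CLIMB": (2.0, 10.0),
    "TUBE": (10.0, 60.0),
    "AGGRESSION": (20.0, 300.0),
}

_DEFAULT_WEIGHTS = {
    "LOCOMOTE": 5.0,
    "REST_SLEEP": 0.5,
    "EAT": 1.0,
    "DRINK": 0.6,
    "REAR": 1.2,
    "CLIMB": 0.7,
    "TUBE": 0.8,
    "AGGRESSION": 0.3,
}

_DEFAULT_SPEED = {
    "LOCOMOTE": (3.0, 12.0),
    "AGGRESSION": (8.0, 12.0),
}


class SimConfig(BaseModel):
    """Study conditions for one simulated session.

    Defaults follow the emulated acquisition regime: 10 frames/s overhead
    video, up to five co-housed mice, contact bundles below 4 cm, tag
    sightings every ~7.5 s on average during activity (never during sleep
    or inside a bundle), and sleep episodes long enough to always satisfy
    the 2-minute inactivity rule.
    """

    model_config = ConfigDict(extra="forbid")

    n_mice: int = Field(default=4, ge=1, le=5)
    duration_s: float = Field(default=3600.0, gt=0)
    fps: float = Field(default=10.0, gt=0)
    seed: int = 0
    geom: CageGeometry = Field(default_factory=CageGeometry)
    cal: Calibration = Field(default_factory=Calibration)
    dwell_s: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(_DEFAULT_DWELL)
    )
    transition_weights: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    diurnal_gain: float = Field(default=2.0, gt=0)
    speed_cm_s: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(_DEFAULT_SPEED)
    )
    bundle_dist_cm: float = Field(default=4.0, ge=0)
    miss_prob: float = Field(default=0.05, ge=0, le=1)
    jitter_px_sd: float = Field(default=2.0, ge=0)
    tag_mean_interval_s: float = Field(default=7.5, gt=0)
    tag_sleep_visible: bool = False
    tag_score_range: tuple[float, float] = (0.85, 1.0)
    det_score_range: tuple[float, float] = (0.85, 1.0)
    area_px: tuple[float, float] = (5400.0, 0.5)  # nominal box area, rear ratio
    session_start_hour: float = 8.0
    light_hours: tuple[float, float] = (8.0, 20.0)
    head_offset_cm: float = 2.5
    exclusion_cm: float = 2.5  # soft body-exclusion distance between animals
    body_half_cm: tuple[float, float] = (3.0, 2.0)
    head_half_cm: tuple[float, float] = (1.25, 1.0)
    turn_sd_rad: float = 0.15
    speed_jitter: float = 0.15  # per-frame fractional speed variation

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for s in STATES:
            if s not in self.dwell_s:
                raise ConfigurationError(f"dwell_s missing state {s}")
            lo, hi = self.dwell_s[s]
            if lo > hi or lo < 0:
                raise ConfigurationError(f"dwell_s[{s}] must satisfy 0 <= min <= max")
            if s not in self.transition_weights:
                raise ConfigurationError(f"transition_weights missing state {s}")
            if self.transition_weights[s] < 0:
                raise ConfigurationError(f"transition_weights[{s}] must be >= 0")
        for rng_ in (self.tag_score_range, self.det_score_range):
            if not (0 <= rng_[0] <= rng_[1] <= 1):
                raise ConfigurationError("score ranges must satisfy 0 <= lo <= hi <= 1")
        if not (0 < self.area_px[1] <= 1):
            raise ConfigurationError("rear foreshortening ratio must be in (0, 1]")
        return self


@dataclass
class SimOutput:
    """Ground truth plus everything the downstream pipeline consumes."""

    truth: pd.DataFrame
    detections: pd.DataFrame
    tags: pd.DataFrame
    annotations: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# ground-truth dynamics


@dataclass
class _Agent:
    pos: np.ndarray
    heading: float
    state: str = "LOCOMOTE"
    phase: str = "in_state"  # in_state | transit | approach
    dwell: int = 0
    target: np.ndarray | None = None
    final_heading: float = 0.0
    pending_state: str = ""
    pending_dwell: int = 0
    partner: int = -1
    role: str = ""  # chaser | evader
    reserved: bool = False
    last_speed: float = 0.0
    seg_speed: float = 6.0
    transit_frames: int = 0
    transit_anchor: np.ndarray | None = None
    forced_next: str = ""


def _dwell_frames(cfg: SimConfig, state: str, rng: np.random.Generator) -> int:
    lo, hi = cfg.dwell_s[state]
    return max(1, round(rng.uniform(lo, hi) * cfg.fps))


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    return v / n if n > 1e-12 else np.array([1.0, 0.0])


def _rect_center(r) -> np.ndarray:
    return np.array([(r[0] + r[2]) / 2, (r[1] + r[3]) / 2])


def _target_for(cfg: SimConfig, state: str, rng: np.random.Generator):
    """Return (body target, final heading) placing the animal so the metric
    engine's geometric rule for the state is satisfied on arrival."""
    g = cfg.geom
    if state == "EAT":
        c = _rect_center(g.hopper_roi)
        half = max(0.5, (g.hopper_roi[2] - g.hopper_roi[0]) / 2 - 1.0)
        body = np.array([c[0] + rng.uniform(-half, half), g.hopper_roi[3] + 1.0])
    elif state == "DRINK":
        c = _rect_center(g.spout_roi)
        body = np.array([c[0] + rng.uniform(-1.0, 1.0), g.spout_roi[3] + 1.0])
    elif state == "CLIMB":
        r = g.hopper_top_roi
        body = np.array([rng.uniform(r[0] + 1.0, r[2] - 1.0), (r[1] + r[3]) / 2])
        return body, -math.pi / 2  # facing the hopper wall (front)
    elif state == "REAR":
        wall = g.rearing_walls[rng.integers(len(g.rearing_walls))]
        w, d = g.floor_width_cm, g.floor_depth_cm
        if wall == "left":
            return np.array([1.0, rng.uniform(1.5, d - 1.5)]), math.pi
        if wall == "right":
            return np.array([w - 1.0, rng.uniform(1.5, d - 1.5)]), 0.0
        if wall == "back":
            return np.array([rng.uniform(1.5, w - 1.5), d - 1.0]), math.pi / 2
        return np.array([rng.uniform(1.5, w - 1.5), 1.0]), -math.pi / 2
    elif state == "TUBE":
        r = g.tube_roi
        body = np.array(
            [rng.uniform(r[0] + 1.0, r[2] - 1.0), rng.uniform(r[1] + 1.0, r[3] - 1.0)]
        )
        return body, rng.uniform(-math.pi, math.pi)
    elif state == "REST_SLEEP":
        # dispersed resting sites away from the feeder wall (so a sleeping
        # head never reaches the hopper/spout ROIs)
        w, d = cfg.geom.floor_width_cm, cfg.geom.floor_depth_cm
        y_lo = min(cfg.head_offset_cm + max(g.hopper_roi[3], g.spout_roi[3]) + 0.5,
                   d - 3.0)
        body = np.array(
            [rng.uniform(3.0, w - 3.0), rng.uniform(y_lo, max(y_lo, d - 3.0))]
        )
        return body, rng.uniform(-math.pi, math.pi)
    else:  # pragma: no cover - LOCOMOTE/AGGRESSION have no fixed target
        raise ValueError(state)
    u = _unit(_rect_center(g.hopper_roi if state == "EAT" else g.spout_roi) - body)
    return body, math.atan2(u[1], u[0])


def _reflect(pos: np.ndarray, heading: float, cfg: SimConfig) -> tuple[np.ndarray, float]:
    w, d = cfg.geom.floor_width_cm, cfg.geom.floor_depth_cm
    hx, hy = math.cos(heading), math.sin(heading)
    if pos[0] < 0.5:
        pos[0] = 1.0 - pos[0]
        hx = -hx
    elif pos[0] > w - 0.5:
        pos[0] = 2 * (w - 0.5) - pos[0]
        hx = -hx
    if pos[1] < 0.5:
        pos[1] = 1.0 - pos[1]
        hy = -hy
    elif pos[1] > d - 0.5:
        pos[1] = 2 * (d - 0.5) - pos[1]
        hy = -hy
    return pos, math.atan2(hy, hx)


def _choose_next(
    cfg: SimConfig, mice: list[_Agent], i: int, dark: bool, rng: np.random.Generator
) -> None:
    m = mice[i]
    if m.reserved:  # a chaser is approaching; stay available
        m.state, m.phase = "LOCOMOTE", "in_state"
        m.dwell = _dwell_frames(cfg, "LOCOMOTE", rng)
        m.seg_speed = rng.uniform(*cfg.speed_cm_s.get("LOCOMOTE", (3.0, 12.0)))
        return
    eligible_partners = [
        j
        for j, o in enumerate(mice)
        if j != i
        and o.state == "LOCOMOTE"
        and o.phase == "in_state"
        and not o.reserved
    ]
    if m.forced_next:
        nxt_forced = m.forced_next
        m.forced_next = ""
        m.target, m.final_heading = _target_for(cfg, nxt_forced, rng)
        m.pending_state = nxt_forced
        m.pending_dwell = _dwell_frames(cfg, nxt_forced, rng)
        m.phase = "transit"
        m.transit_frames = 0
        m.transit_anchor = None
        return
    weights = []
    for s in STATES:
        wgt = cfg.transition_weights[s]
        if s == m.state:
            wgt = 0.0
        if s == "AGGRESSION" and (cfg.n_mice == 1 or not eligible_partners):
            wgt = 0.0
        if dark and s in _ACTIVE:
            wgt *= cfg.diurnal_gain
        weights.append(wgt)
    weights = np.asarray(weights)
    if weights.sum() <= 0:
        nxt = "LOCOMOTE"
    else:
        nxt = STATES[rng.choice(len(STATES), p=weights / weights.sum())]
    if nxt == "LOCOMOTE":
        m.state, m.phase = "LOCOMOTE", "in_state"
        m.dwell = _dwell_frames(cfg, "LOCOMOTE", rng)
        m.heading = rng.uniform(-math.pi, math.pi)
        m.seg_speed = rng.uniform(*cfg.speed_cm_s.get("LOCOMOTE", (3.0, 12.0)))
    elif nxt == "REST_SLEEP" or m.state == "REST_SLEEP":
        # animals wander briefly before settling down to rest and after
        # waking; this separates fixture dwell from the rest bout proper
        m.state, m.phase = "LOCOMOTE", "in_state"
        m.dwell = max(1, round(rng.uniform(3.0, 8.0) * cfg.fps))
        m.heading = rng.uniform(-math.pi, math.pi)
        m.seg_speed = rng.uniform(*cfg.speed_cm_s.get("LOCOMOTE", (3.0, 12.0)))
        if nxt not in ("LOCOMOTE", "AGGRESSION"):
            m.forced_next = nxt
    elif nxt == "AGGRESSION":
        j = int(eligible_partners[rng.integers(len(eligible_partners))])
        m.phase, m.role, m.partner = "approach", "chaser", j
        m.pending_dwell = _dwell_frames(cfg, "AGGRESSION", rng)
        mice[j].reserved = True
    else:
        m.target, m.final_heading = _target_for(cfg, nxt, rng)
        m.pending_state, m.pending_dwell = nxt, _dwell_frames(cfg, nxt, rng)
        m.phase = "transit"
        m.transit_frames = 0
        m.transit_anchor = None


def _simulate_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n, fps, dt = cfg.n_mice, cfg.fps, 1.0 / cfg.fps
    n_frames = round(cfg.duration_s * cfg.fps)
    w, d = cfg.geom.floor_width_cm, cfg.geom.floor_depth_cm
    nominal, rear_ratio = cfg.area_px

    lo_lo, lo_hi = cfg.speed_cm_s.get("LOCOMOTE", (3.0, 12.0))
    ag_lo, ag_hi = cfg.speed_cm_s.get("AGGRESSION", (8.0, 12.0))
    light_lo, light_hi = cfg.light_hours

    mice = [
        _Agent(
            pos=np.array([rng.uniform(3, w - 3), rng.uniform(3, d - 3)]),
            heading=rng.uniform(-math.pi, math.pi),
        )
        for _ in range(n)
    ]
    for m in mice:
        m.dwell = _dwell_frames(cfg, "LOCOMOTE", rng)
        m.seg_speed = rng.uniform(lo_lo, lo_hi)

    X = np.empty((n_frames, n))
    Y = np.empty((n_frames, n))
    HD = np.empty((n_frames, n))
    AREA = np.empty((n_frames, n))
    ST = np.empty((n_frames, n), dtype=np.int8)

    for f in range(n_frames):
        hour = (cfg.session_start_hour + f * dt / 3600.0) % 24.0
        dark = not (light_lo <= hour < light_hi)

        # 1. state transitions
        for i, m in enumerate(mice):
            if m.phase == "transit":
                m.transit_frames += 1
                stalled = False
                if m.transit_frames % 10 == 0:
                    if m.transit_anchor is not None:
                        stalled = np.hypot(*(m.pos - m.transit_anchor)) < 1.0
                    m.transit_anchor = m.pos.copy()
                # arrival, or blocked by a cage mate occupying the target
                if np.hypot(*(m.target - m.pos)) <= 1.0 or stalled:
                    if not stalled:
                        m.pos = m.target.copy()  # settle onto the goal
                    m.state, m.phase = m.pending_state, "in_state"
                    m.dwell = m.pending_dwell
                    m.heading = m.final_heading
                    m.transit_frames = 0
                    m.transit_anchor = None
            elif m.phase == "approach":
                p = mice[m.partner]
                if np.hypot(*(p.pos - m.pos)) <= 4.95:
                    m.state, m.phase = "AGGRESSION", "in_state"
                    m.dwell = m.pending_dwell
                    p.state, p.phase, p.role = "AGGRESSION", "in_state", "evader"
                    p.partner, p.reserved = i, False
                    p.seg_speed = rng.uniform(ag_lo, ag_hi)
            elif m.state == "AGGRESSION":
                if m.role == "chaser":
                    m.dwell -= 1
                    if m.dwell <= 0:
                        away = _unit(m.pos - mice[m.partner].pos)
                        for k, sgn in ((i, 1.0), (m.partner, -1.0)):
                            o = mice[k]
                            o.state, o.phase, o.role = "LOCOMOTE", "in_state", ""
                            o.partner = -1
                            o.dwell = _dwell_frames(cfg, "LOCOMOTE", rng)
                            o.seg_speed = rng.uniform(lo_lo, lo_hi)
                            # combatants disengage away from each other
                            o.heading = math.atan2(sgn * away[1], sgn * away[0])
            else:
                m.dwell -= 1
                if m.dwell <= 0:
                    _choose_next(cfg, mice, i, dark, rng)

        # 2. motion: evaders first so chasers see fresh positions
        order = sorted(
            range(n), key=lambda k: 0 if mice[k].role != "chaser" else 1
        )
        for i in order:
            m = mice[i]
            if m.phase == "transit" or m.phase == "approach":
                target = mice[m.partner].pos if m.phase == "approach" else m.target
                v = target - m.pos
                dist = float(np.hypot(v[0], v[1]))
                speed = 14.0 if m.phase == "approach" else lo_hi
                step = min(speed * dt, dist)
                if dist > 1e-9:
                    u = v / dist
                    m.pos = m.pos + step * u
                    m.heading = math.atan2(u[1], u[0])
                m.last_speed = step / dt
            elif m.state == "LOCOMOTE":
                m.heading += rng.normal(0.0, cfg.turn_sd_rad)
                speed = float(np.clip(
                    m.seg_speed * (1.0 + rng.normal(0.0, cfg.speed_jitter)),
                    lo_lo, lo_hi,
                ))
                m.pos = m.pos + speed * dt * np.array(
                    [math.cos(m.heading), math.sin(m.heading)]
                )
                m.pos, m.heading = _reflect(m.pos, m.heading, cfg)
                m.last_speed = speed
            elif m.state == "AGGRESSION" and m.role == "evader":
                m.heading += rng.normal(0.0, cfg.turn_sd_rad)
                speed = float(np.clip(
                    m.seg_speed * (1.0 + rng.normal(0.0, cfg.speed_jitter)),
                    ag_lo, ag_hi,
                ))
                m.pos = m.pos + speed * dt * np.array(
                    [math.cos(m.heading), math.sin(m.heading)]
                )
                m.pos, m.heading = _reflect(m.pos, m.heading, cfg)
                m.last_speed = speed
            elif m.state == "AGGRESSION":  # chaser keeps a ~4.5 cm pursuit gap
                p = mice[m.partner]
                v = p.pos - m.pos
                dist = float(np.hypot(v[0], v[1]))
                step = min(max(dist - 4.5, 0.0), p.last_speed * 1.25 * dt)
                if dist > 1e-9 and step > 0:
                    u = v / dist
                    m.pos = m.pos + step * u
                    m.heading = math.atan2(u[1], u[0])
                m.last_speed = step / dt
            else:
                m.last_speed = 0.0

        # 3. body exclusion: animals cannot occupy the same spot; overlapping
        # pairs are pushed apart symmetrically (two passes settle triples)
        if n > 1 and cfg.exclusion_cm > 0:
            for _ in range(2):
                for i in range(n):
                    for j2 in range(i + 1, n):
                        v = mice[i].pos - mice[j2].pos
                        dist2 = float(np.hypot(v[0], v[1]))
                        if dist2 < cfg.exclusion_cm:
                            if dist2 < 1e-6:
                                v = np.array(
                                    [math.cos(mice[i].heading),
                                     math.sin(mice[i].heading)]
                                )
                                dist2 = 1.0
                            push = (cfg.exclusion_cm - dist2) / 2 * (v / dist2)
                            for mm, sgn in ((mice[i], 1.0), (mice[j2], -1.0)):
                                mm.pos = mm.pos + sgn * push
                                mm.pos[0] = min(max(mm.pos[0], 0.5), w - 0.5)
                                mm.pos[1] = min(max(mm.pos[1], 0.5), d - 0.5)

        # 4. record
        for i, m in enumerate(mice):
            rec_state = m.state if m.phase == "in_state" else "LOCOMOTE"
            X[f, i], Y[f, i] = m.pos
            HD[f, i] = math.degrees(m.heading)
            AREA[f, i] = nominal * (rear_ratio if rec_state in ("REAR", "CLIMB") else 1.0)
            ST[f, i] = STATES.index(rec_state)

    frames = np.repeat(np.arange(n_frames), n)
    ids = np.tile(np.arange(1, n + 1), n_frames)
    return pd.DataFrame(
        {
            "frame": frames,
            "mouse_id": ids,
            "x_cm": X.ravel(),
            "y_cm": Y.ravel(),
            "head_dir_deg": HD.ravel(),
            "state": np.asarray(STATES, dtype=object)[ST.ravel()],
            "area_px": AREA.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# degradation to detections, tags, annotations


def _truth_grids(truth: pd.DataFrame):
    """Pivot a complete truth table to (n_frames, n_mice) arrays."""
    ids = np.sort(truth["mouse_id"].unique())
    t = truth.sort_values(["frame", "mouse_id"])
    n = len(ids)
    n_frames = t["frame"].nunique()
    shape = (n_frames, n)
    return (
        ids,
        t["x_cm"].to_numpy().reshape(shape),
        t["y_cm"].to_numpy().reshape(shape),
        t["head_dir_deg"].to_numpy().reshape(shape),
        t["area_px"].to_numpy().reshape(shape),
        t["state"].to_numpy().reshape(shape),
    )


def bundle_labels(truth: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Per-frame contact-group label for each mouse: -1 for a lone animal,
    otherwise a small nonnegative group index (pairwise centroid distance
    below ``bundle_dist_cm`` links animals into one group)."""
    _, X, Y, *_ = _truth_grids(truth)
    n_frames, n = X.shape
    labels = np.full((n_frames, n), -1, dtype=np.int8)
    if n < 2 or config.bundle_dist_cm <= 0:
        return labels
    dx = X[:, :, None] - X[:, None, :]
    dy = Y[:, :, None] - Y[:, None, :]
    adj = (dx * dx + dy * dy) < config.bundle_dist_cm**2
    for i in range(n):
        adj[:, i, i] = False
    has_pair = adj.any(axis=(1, 2))
    for f in np.nonzero(has_pair)[0]:
        a = adj[f]
        seen = np.zeros(n, dtype=bool)
        g = 0
        for i in range(n):
            if seen[i]:
                continue
            stack, comp = [i], [i]
            seen[i] = True
            while stack:
                k = stack.pop()
                for j in np.nonzero(a[k])[0]:
                    if not seen[j]:
                        seen[j] = True
                        stack.append(j)
                        comp.append(j)
            if len(comp) > 1:
                labels[f, comp] = g
                g += 1
    return labels


def _head_pos_cm(x, y, hd_deg, offset):
    rad = np.deg2rad(hd_deg)
    return x + offset * np.cos(rad), y + offset * np.sin(rad)


def degrade_to_detections(
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Replace contact groups by single bundle detections, drop detections
    at ``miss_prob``, and jitter box corners with sd ``jitter_px_sd``."""
    if labels is None:
        labels = bundle_labels(truth, config)
    _, X, Y, HD, AREA, _ = _truth_grids(truth)
    n_frames, n = X.shape
    cal, nominal = config.cal, config.area_px[0]
    hw0, hh0 = config.body_half_cm
    hhw, hhh = config.head_half_cm

    def body_box_px(x, y, area):
        s = np.sqrt(area / nominal)
        cx = x * cal.px_per_cm_x + cal.origin_px[0]
        cy = y * cal.px_per_cm_y + cal.origin_px[1]
        ex = hw0 * s * cal.px_per_cm_x
        ey = hh0 * s * cal.px_per_cm_y
        return cx - ex, cy - ey, cx + ex, cy + ey

    single = labels < 0
    f_idx, m_idx = np.nonzero(single)
    keep = rng.random(len(f_idx)) >= config.miss_prob
    f_idx, m_idx = f_idx[keep], m_idx[keep]
    x, y = X[f_idx, m_idx], Y[f_idx, m_idx]
    bx1, by1, bx2, by2 = body_box_px(x, y, AREA[f_idx, m_idx])
    hx, hy = _head_pos_cm(x, y, HD[f_idx, m_idx], config.head_offset_cm)
    hcx = hx * cal.px_per_cm_x + cal.origin_px[0]
    hcy = hy * cal.px_per_cm_y + cal.origin_px[1]
    hx1, hy1 = hcx - hhw * cal.px_per_cm_x, hcy - hhh * cal.px_per_cm_y
    hx2, hy2 = hcx + hhw * cal.px_per_cm_x, hcy + hhh * cal.px_per_cm_y
    cols = np.stack([bx1, by1, bx2, by2, hx1, hy1, hx2, hy2], axis=1)
    cols += rng.normal(0.0, config.jitter_px_sd, size=cols.shape)
    singles = pd.DataFrame(
        cols,
        columns=[
            "body_x1", "body_y1", "body_x2", "body_y2",
            "head_x1", "head_y1", "head_x2", "head_y2",
        ],
    )
    singles.insert(0, "frame", f_idx)
    singles["score"] = rng.uniform(*config.det_score_range, size=len(singles))
    singles["is_bundle"] = False
    singles["member_count"] = np.nan

    rows = []
    bundle_frames = np.nonzero((labels >= 0).any(axis=1))[0]
    for f in bundle_frames:
        for g in np.unique(labels[f][labels[f] >= 0]):
            members = np.nonzero(labels[f] == g)[0]
            if rng.random() < config.miss_prob:
                continue
            boxes = np.array(
                [body_box_px(X[f, i], Y[f, i], AREA[f, i]) for i in members]
            )
            box = [
                boxes[:, 0].min(), boxes[:, 1].min(),
                boxes[:, 2].max(), boxes[:, 3].max(),
            ]
            box = list(np.asarray(box) + rng.normal(0, config.jitter_px_sd, 4))
            rows.append(
                [f, *box, np.nan, np.nan, np.nan, np.nan,
                 rng.uniform(*config.det_score_range), True, float(len(members))]
            )
    if rows:
        bundles = pd.DataFrame(rows, columns=singles.columns)
        out = pd.concat([singles, bundles], ignore_index=True)
    else:
        out = singles
    out = out.sort_values(["frame", "is_bundle", "body_x1"], kind="stable")
    return out.reset_index(drop=True)


def emit_tag_observations(
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exponential-gap ear-tag sightings per animal, suppressed during sleep
    (unless ``tag_sleep_visible``) and while the animal is inside a bundle."""
    if labels is None:
        labels = bundle_labels(truth, config)
    ids, X, Y, HD, _, STATE = _truth_grids(truth)
    n_frames, n = X.shape
    cal = config.cal
    rows = []
    for i in range(n):
        k = int(config.duration_s / config.tag_mean_interval_s * 2 + 20)
        times = np.cumsum(rng.exponential(config.tag_mean_interval_s, size=k))
        times = times[times < config.duration_s]
        frames = np.unique((times * config.fps).astype(int))
        frames = frames[frames < n_frames]
        ok = labels[frames, i] < 0
        if not config.tag_sleep_visible:
            ok &= STATE[frames, i] != "REST_SLEEP"
        frames = frames[ok]
        hx, hy = _head_pos_cm(
            X[frames, i], Y[frames, i], HD[frames, i], config.head_offset_cm
        )
        px = hx * cal.px_per_cm_x + cal.origin_px[0] + rng.normal(0, 1.0, len(frames))
        py = hy * cal.px_per_cm_y + cal.origin_px[1] + rng.normal(0, 1.0, len(frames))
        score = rng.uniform(*config.tag_score_range, size=len(frames))
        for f, x_, y_, s_ in zip(frames, px, py, score):
            rows.append([int(f), int(ids[i]), x_, y_, s_])
    out = pd.DataFrame(rows, columns=["frame", "tag_id", "x", "y", "score"])
    out = out.sort_values(["frame", "tag_id"], kind="stable")
    return out.reset_index(drop=True)


def trajectory_from_truth(
    truth: pd.DataFrame, head_offset_cm: float = 2.5
) -> pd.DataFrame:
    """Repackage ground truth as a noiseless, fully detected trajectory
    table (the metric engine's input format)."""
    hx, hy = _head_pos_cm(
        truth["x_cm"].to_numpy(),
        truth["y_cm"].to_numpy(),
        truth["head_dir_deg"].to_numpy(),
        head_offset_cm,
    )
    out = pd.DataFrame(
        {
            "frame": truth["frame"].to_numpy(),
            "mouse_id": truth["mouse_id"].to_numpy(),
            "x_cm": truth["x_cm"].to_numpy(),
            "y_cm": truth["y_cm"].to_numpy(),
            "head_x_cm": hx,
            "head_y_cm": hy,
            "head_dir_deg": truth["head_dir_deg"].to_numpy(),
            "area_px": truth["area_px"].to_numpy(),
            "status": "detected",
        }
    )
    return out.sort_values(["frame", "mouse_id"], kind="stable").reset_index(drop=True)


def simulate_session(config: SimConfig) -> SimOutput:
    """Run one fully deterministic simulated session.

    Separate named random sub-streams drive motion, detection noise and tag
    sightings, so each can be varied independently under one seed.
    """
    ss = np.random.SeedSequence(config.seed)
    motion_rng, noise_rng, tag_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    truth = _simulate_truth(config, motion_rng)
    labels = bundle_labels(truth, config)
    detections = degrade_to_detections(truth, config, noise_rng, labels)
    tags = emit_tag_observations(truth, config, tag_rng, labels)
    annotations = truth[["frame", "mouse_id"]].copy()
    annotations["behavior"] = truth["state"].str.lower()
    return SimOutput(
        truth=truth,
        detections=detections,
        tags=tags,
        annotations=annotations,
        config=config,
    )
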