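"""Tracking-by-detection with identity maintenance for group-housed mice.

The tracker consumes per-frame bounding-box detections (including merged
"bundle" detections covering animals in contact) and sparse ear-tag
sightings, and emits one identity-resolved row per declared animal per
frame. The declared roster is treated as ground truth: exactly
``n_declared`` identities exist at all times, detections beyond the roster
are ignored, and missing detections are coasted with a damped
constant-velocity prediction.

Identity switches are conservative: they only ever originate from ear-tag
evidence (two independent high-confidence mismatching sightings by
default), never from the association step itself. A committed switch is
applied retroactively back to the most recent frame at which the two
animals were mutually ambiguous (within the association gate of each
other, e.g. inside a shared bundle), searching backward from the first
mismatching sighting and capped at a configurable horizon.

While animals share a bundle their identities are frozen. Each member is
held at its own damped prediction clipped into the bundle box, so the
entry geometry (who is ahead, who trails) is carried through the occlusion
by the members' motion state rather than by appearance. On dissolution the
emerging detections are re-bound to members by minimum-total-distance
assignment from the held positions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy.optimize import linear_sum_assignment

from .geometry import CageGeometry, Calibration, ConfigurationError

_BIG = 1e7
STATUS_NAMES = np.array(["detected", "propagated", "bundled"], dtype=object)


class TrackingError(RuntimeError):
    """Raised for unusable detection input (empty table, unsorted frames)."""


@dataclass(frozen=True)
class Roster:
    """User-declared animal identities; treated as ground truth for count."""

    declared_ids: frozenset[int]

    def __post_init__(self):
        if len(self.declared_ids) < 1:
            raise ConfigurationError("roster must declare at least one id")

    @property
    def n_declared(self) -> int:
        return len(self.declared_ids)

    @property
    def sorted_ids(self) -> list[int]:
        return sorted(self.declared_ids)


class TrackerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gate_cm: float = Field(default=6.0, gt=0)
    vel_damping: float = Field(default=0.9, gt=0, le=1)
    switch_evidence_k: int = Field(default=2, ge=2)
    tag_score_min: float = Field(default=0.8, ge=0, le=1)
    retro_horizon_s: float = Field(default=300.0, gt=0)
    # multiplicative weights on association cost: detection-score term and
    # trajectory-consistency term (cost inflation near the gate edge)
    confidence_multipliers: dict[str, float] = Field(
        default_factory=lambda: {"score": 0.5, "trajectory": 0.0}
    )
    reacquire_after_frames: int = Field(default=5, ge=1)
    max_speed_cm_s: float = Field(default=40.0, gt=0)
    # members held inside a bundle keep their motion longer than coasting
    # tracklets, and are granted a wider re-association gate on emergence
    bundle_vel_damping: float = Field(default=0.97, gt=0, le=1)
    bundle_exit_gate_mult: float = Field(default=2.0, ge=1)
    # reported member positions decay toward the bundle centroid (per-frame
    # factor): within-blob certainty fades the longer the occlusion lasts
    bundle_offset_decay: float = Field(default=0.93, gt=0, le=1)

    @field_validator("confidence_multipliers")
    @classmethod
    def _known_keys(cls, v):
        unknown = set(v) - {"score", "trajectory"}
        if unknown:
            raise ConfigurationError(f"unknown confidence multipliers: {unknown}")
        return v


@dataclass
class TrackletState:
    current_id: int
    pos_cm: np.ndarray
    vel_cm_s: np.ndarray
    frames_since_seen: int = 0
    in_bundle: bool = False
    confidence: float = 0.0
    head_offset_cm: np.ndarray | None = None
    area_px: float = float("nan")
    status: int = 0  # index into STATUS_NAMES
    last_box: np.ndarray | None = None  # bundle box tracked last frame
    bundle_frames: int = 0  # consecutive frames held inside a bundle
    emit_pos: np.ndarray | None = None  # reported position while bundled
    confirmed: bool = False  # identity has been corroborated by a tag


@dataclass
class PendingIdentityEvidence:
    tracklet_ref: int
    candidate_id: int
    evidence_count: int
    first_frame: int


@dataclass
class TrackResult:
    trajectory: pd.DataFrame
    relabel_count: int
    discrepancy_flag: bool
    ledger: list[PendingIdentityEvidence] = field(default_factory=list)


def predict_position(
    t: TrackletState, dt: float, config: TrackerConfig, geom: CageGeometry
) -> np.ndarray:
    """Damped constant-velocity prediction, clamped to the floor rectangle."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = t.pos_cm + t.vel_cm_s * (config.vel_damping**t.frames_since_seen) * dt
    p[0] = min(max(p[0], 0.0), geom.floor_width_cm)
    p[1] = min(max(p[1], 0.0), geom.floor_depth_cm)
    return p


def associate(
    predictions: np.ndarray,
    detections: np.ndarray,
    gate_cm: float,
    det_scores: np.ndarray | None = None,
    score_weight: float = 0.0,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-total-cost one-to-one assignment with a hard distance gate.

    Cost is the prediction-to-detection distance, optionally inflated for
    low-scoring detections. Pairs beyond ``gate_cm`` are forbidden. Returns
    (matched pairs, unmatched prediction indices, unmatched detection
    indices).
    """
    pred = np.atleast_2d(np.asarray(predictions, dtype=float))
    det = np.atleast_2d(np.asarray(detections, dtype=float))
    if pred.size == 0 or det.size == 0:
        return [], list(range(len(pred))), list(range(len(det)))
    gate = np.broadcast_to(
        np.asarray(gate_cm, dtype=float), (len(pred),)
    )[:, None]
    d = np.linalg.norm(pred[:, None, :] - det[None, :, :], axis=2)
    cost = d.copy()
    if det_scores is not None and score_weight:
        cost = cost * (1.0 + score_weight * (1.0 - np.asarray(det_scores))[None, :])
    cost[d > gate] = _BIG
    ri, ci = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(ri, ci) if d[i, j] <= gate[i, 0]]
    mp = {i for i, _ in pairs}
    md = {j for _, j in pairs}
    return (
        pairs,
        [i for i in range(len(pred)) if i not in mp],
        [j for j in range(len(det)) if j not in md],
    )


# ---------------------------------------------------------------------------
# detection table preparation


def _prepare_detections(detections: pd.DataFrame, cal: Calibration):
    """Convert the px detection table to cm centroid/box arrays by frame."""
    req = {"frame", "body_x1", "body_y1", "body_x2", "body_y2", "score", "is_bundle"}
    missing = req - set(detections.columns)
    if missing:
        raise TrackingError(f"detection table missing columns: {sorted(missing)}")
    if len(detections) == 0:
        raise TrackingError("empty detection table")
    frames = detections["frame"].to_numpy()
    if np.any(np.diff(frames) < 0):
        raise TrackingError("detection frames are not sorted")
    sx, sy = cal.px_per_cm_x, cal.px_per_cm_y
    ox, oy = cal.origin_px
    x1 = (detections["body_x1"].to_numpy() - ox) / sx
    x2 = (detections["body_x2"].to_numpy() - ox) / sx
    y1 = (detections["body_y1"].to_numpy() - oy) / sy
    y2 = (detections["body_y2"].to_numpy() - oy) / sy
    box = np.stack(
        [np.minimum(x1, x2), np.minimum(y1, y2),
         np.maximum(x1, x2), np.maximum(y1, y2)], axis=1
    )
    pos = np.stack([(x1 + x2) / 2, (y1 + y2) / 2], axis=1)
    area = np.abs(
        (detections["body_x2"] - detections["body_x1"])
        * (detections["body_y2"] - detections["body_y1"])
    ).to_numpy()
    if {"head_x1", "head_y1", "head_x2", "head_y2"} <= set(detections.columns):
        hx = (detections["head_x1"].to_numpy() + detections["head_x2"].to_numpy()) / 2
        hy = (detections["head_y1"].to_numpy() + detections["head_y2"].to_numpy()) / 2
        head = np.stack([(hx - ox) / sx, (hy - oy) / sy], axis=1)
    else:
        head = np.full((len(detections), 2), np.nan)
    is_bundle = detections["is_bundle"].to_numpy().astype(bool)
    members = (
        detections["member_count"].to_numpy(dtype=float)
        if "member_count" in detections.columns
        else np.full(len(detections), np.nan)
    )
    score = detections["score"].to_numpy(dtype=float)
    return frames, pos, box, head, area, score, is_bundle, members


def initialize_tracks(
    first_positions: np.ndarray,
    tags_near_start: list[tuple[int, np.ndarray]],
    roster: Roster,
    gate_cm: float,
) -> list[int]:
    """Bind declared ids to initial candidate positions.

    Tag sightings near session start take precedence; remaining ids are
    bound deterministically, sorted id to sorted x-coordinate.
    """
    n = len(first_positions)
    assigned: list[int | None] = [None] * n
    used: set[int] = set()
    for tag_id, p in tags_near_start:
        if tag_id in used or tag_id not in roster.declared_ids:
            continue
        d = np.linalg.norm(first_positions - p[None, :], axis=1)
        d[[i for i in range(n) if assigned[i] is not None]] = np.inf
        j = int(np.argmin(d))
        if d[j] <= gate_cm:
            assigned[j] = tag_id
            used.add(tag_id)
    rest = [i for i in roster.sorted_ids if i not in used]
    open_slots = sorted(
        (i for i in range(n) if assigned[i] is None),
        key=lambda i: (first_positions[i][0], first_positions[i][1]),
    )
    for slot, tid in zip(open_slots, rest):
        assigned[slot] = tid
    return assigned


def _clip_to_box(p: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.array(
        [min(max(p[0], box[0]), box[2]), min(max(p[1], box[1]), box[3])]
    )


def _point_box_dist(p: np.ndarray, box: np.ndarray) -> float:
    dx = max(box[0] - p[0], 0.0, p[0] - box[2])
    dy = max(box[1] - p[1], 0.0, p[1] - box[3])
    return math.hypot(dx, dy)


class _Session:
    """Mutable per-session tracker state (identity ledger + retro repair)."""

    def __init__(self, roster, config, fps, n_frames):
        self.roster = roster
        self.cfg = config
        self.fps = fps
        self.relabel_count = 0
        self.ledger: dict[tuple[int, int], list[int]] = {}  # (slot, cand) -> [n, f0]
        self.last_confirm: dict[int, int] = {i: 0 for i in roster.sorted_ids}
        self.id_arrival: dict[int, int] = {i: 0 for i in roster.sorted_ids}
        self.tracklets: list[TrackletState] = []
        self.ids = None
        self.xs = None
        self.ys = None

    def _ambiguity_frame(self, f, first_evidence_f, sa, sb, id_a, id_b):
        """Most recent frame at which slots sa and sb were within the gate
        of each other, searching backward from the first mismatching tag
        sighting (identities were already wrong by then). The search floor
        is the earlier of the two ids' last consistent sightings - the swap
        must postdate the last time either id was positively confirmed -
        bounded by the retro horizon."""
        horizon = int(self.cfg.retro_horizon_s * self.fps)
        anchor = min(self.last_confirm[id_a], self.last_confirm[id_b])
        lo = max(0, f - horizon, anchor)
        hi = min(f, max(first_evidence_f, lo))
        if hi <= lo:
            return lo
        dx = self.xs[lo:hi, sa] - self.xs[lo:hi, sb]
        dy = self.ys[lo:hi, sa] - self.ys[lo:hi, sb]
        close = (dx * dx + dy * dy) <= self.cfg.gate_cm**2
        # a swap can only be born while at least one of the two was not
        # cleanly detected (held in a bundle or coasting) AND at least one
        # was moving - two resting animals cannot exchange bodies
        unclean = (self.status[lo:hi, sa] != 0) | (self.status[lo:hi, sb] != 0)
        moving = np.zeros(hi - lo, dtype=bool)
        for sx_ in (sa, sb):
            px_ = self.xs[max(lo - 3, 0):hi, sx_]
            py_ = self.ys[max(lo - 3, 0):hi, sx_]
            disp = np.hypot(px_[3:] - px_[:-3], py_[3:] - py_[:-3]) if len(px_) > 3 else np.zeros(0)
            disp = np.pad(disp, (max(0, (hi - lo) - len(disp)), 0))
            moving |= disp > 1.0
        idx = np.nonzero(close & unclean & moving)[0]
        cand = lo + int(idx[-1]) if len(idx) else lo
        return cand

    def _exchange_ids(self, f0, f, id_a, id_b):
        """Retroactively exchange two id values wherever they appear in
        [f0, f). Value-based rewriting stays consistent even when other
        swaps were committed inside the window."""
        win = self.ids[f0:f]
        m_a = win == id_a
        m_b = win == id_b
        win[m_a] = id_b
        win[m_b] = id_a

    def _commit_swap(self, f, slot, cand_id, first_evidence_f):
        other = next(
            s for s, t in enumerate(self.tracklets) if t.current_id == cand_id
        )
        a = self.tracklets[slot].current_id
        f0 = self._ambiguity_frame(f, first_evidence_f, slot, other, a, cand_id)
        # an id displaced onto its slot by a previous commit cannot have
        # been mis-paired before it arrived there
        f0 = min(f, max(f0, self.id_arrival[a], self.id_arrival[cand_id]))
        self._exchange_ids(f0, f, a, cand_id)
        self.tracklets[slot].current_id = cand_id
        self.tracklets[other].current_id = a
        self.last_confirm[a] = f
        self.last_confirm[cand_id] = f
        self.id_arrival[a] = f
        self.id_arrival[cand_id] = f
        # evidence about which tag sits on a tracklet stays valid across
        # other swaps; drop only what this swap resolved or made consistent
        self.ledger = {
            k: v for k, v in self.ledger.items()
            if k[0] != slot and k != (other, a)
        }
        self.relabel_count += 1

    def apply_tag_observation(self, f, tag_id, pos_cm, score):
        """Bind a tag sighting to the nearest non-bundled tracklet within
        the gate; consistent sightings clear pending evidence, mismatching
        high-confidence sightings accumulate it, and the k-th mismatch
        commits a retroactive identity swap."""
        if tag_id not in self.roster.declared_ids:
            warnings.warn(f"tag id {tag_id} not in roster; observation rejected")
            return
        best, best_d = -1, np.inf
        for s, t in enumerate(self.tracklets):
            if t.in_bundle:
                continue
            ref = t.pos_cm
            if t.head_offset_cm is not None:
                ref = t.pos_cm + t.head_offset_cm
            d = float(np.hypot(*(ref - pos_cm)))
            if d < best_d:
                best, best_d = s, d
        if best < 0 or best_d > self.cfg.gate_cm:
            return
        t = self.tracklets[best]
        if t.current_id == tag_id:
            t.confidence += 1.0
            t.confirmed = True
            self.last_confirm[tag_id] = f
            self.ledger = {k: v for k, v in self.ledger.items() if k[0] != best}
            return
        if score < self.cfg.tag_score_min:
            return
        holder = next(
            s for s, tt in enumerate(self.tracklets) if tt.current_id == tag_id
        )
        if not (t.confirmed and self.tracklets[holder].confirmed):
            # one of the labels is still provisional (never corroborated by
            # a tag): the sighting completes the tag-based assignment rather
            # than overturning evidence, so it binds immediately and the
            # whole provisional segment is relabeled
            a = t.current_id
            # repair the provisional segment: the whole history when neither
            # id was ever corroborated, else back to the anchored ambiguity
            if self.last_confirm[a] == 0 and self.last_confirm[tag_id] == 0:
                f0 = 0
            else:
                f0 = self._ambiguity_frame(f, f, best, holder, a, tag_id)
            if self.last_confirm[a] > 0 or self.last_confirm[tag_id] > 0:
                f0 = min(f, max(f0, self.id_arrival[a], self.id_arrival[tag_id]))
            self._exchange_ids(f0, f, a, tag_id)
            t.current_id, self.tracklets[holder].current_id = tag_id, a
            t.confirmed = True
            self.last_confirm[tag_id] = f
            self.id_arrival[a] = f
            self.id_arrival[tag_id] = f
            self.tracklets[holder].confirmed = False
            self.ledger = {
                k: v for k, v in self.ledger.items()
                if k[0] != best and k != (holder, a)
            }
            self.relabel_count += 1
            return
        # "tag t keeps appearing on this tracklet": evidence keyed by
        # (tracklet, tag). The sighting of the other animal of a swapped
        # pair produces the symmetric entry; both support the same switch,
        # so they are pooled when checking the threshold.
        key = (best, tag_id)
        if key not in self.ledger:
            self.ledger[key] = [0, f]
        self.ledger[key][0] += 1
        sym = self.ledger.get((holder, t.current_id))
        total = self.ledger[key][0] + (sym[0] if sym else 0)
        if total >= self.cfg.switch_evidence_k:
            first = min(self.ledger[key][1], sym[1] if sym else f)
            self._commit_swap(f, best, tag_id, first)


def track_session(
    detections: pd.DataFrame,
    tags: pd.DataFrame | None,
    roster: Roster,
    cal: Calibration,
    config: TrackerConfig | None = None,
    geom: CageGeometry | None = None,
    fps: float = 10.0,
) -> TrackResult:
    """Run the full per-frame loop: predict, associate, resolve bundles,
    apply tag observations; emit exactly ``n_declared`` rows per frame."""
    config = config or TrackerConfig()
    geom = geom or CageGeometry()
    frames, pos, box, head, area, score, is_bundle, members = _prepare_detections(
        detections, cal
    )
    n = roster.n_declared
    n_frames = int(frames.max()) + 1
    dt = 1.0 / fps
    ses = _Session(roster, config, fps, n_frames)

    det_start = np.searchsorted(frames, np.arange(n_frames + 1))
    if tags is not None and len(tags):
        tf = tags["frame"].to_numpy()
        order = np.argsort(tf, kind="stable")
        tag_frames = tf[order]
        tag_ids = tags["tag_id"].to_numpy()[order]
        tx = (tags["x"].to_numpy() - cal.origin_px[0]) / cal.px_per_cm_x
        ty = (tags["y"].to_numpy() - cal.origin_px[1]) / cal.px_per_cm_y
        tag_pos = np.stack([tx, ty], axis=1)[order]
        tag_scores = tags["score"].to_numpy()[order]
        tag_start = np.searchsorted(tag_frames, np.arange(n_frames + 1))
    else:
        tag_start = None

    # ---- initialization from the first detection frame ----
    ff = int(frames[0])
    init_pos = []
    for j in range(det_start[ff], det_start[ff + 1]):
        if is_bundle[j]:
            cnt = int(members[j]) if np.isfinite(members[j]) else 2
            for k in range(cnt):
                init_pos.append(pos[j] + np.array([0.5 * (k - (cnt - 1) / 2), 0.0]))
        else:
            init_pos.append(pos[j])
    init_pos = init_pos[:n]
    while len(init_pos) < n:  # fewer detections than declared animals
        init_pos.append(
            np.array([geom.floor_width_cm / 2, geom.floor_depth_cm / 2])
        )
    init_pos = np.asarray(init_pos)
    tags_near_start = []
    if tag_start is not None:
        hi = min(n_frames, ff + int(2 * fps))
        for j in range(tag_start[ff], tag_start[hi]):
            tags_near_start.append((int(tag_ids[j]), tag_pos[j]))
    assigned = initialize_tracks(init_pos, tags_near_start, roster, config.gate_cm)
    ses.tracklets = [
        TrackletState(
            current_id=assigned[i], pos_cm=init_pos[i].copy(), vel_cm_s=np.zeros(2)
        )
        for i in range(n)
    ]
    trk = ses.tracklets

    # ---- output arrays ----
    ids = np.empty((n_frames, n), dtype=np.int64)
    xs = np.empty((n_frames, n))
    ys = np.empty((n_frames, n))
    hxs = np.full((n_frames, n), np.nan)
    hys = np.full((n_frames, n), np.nan)
    hds = np.full((n_frames, n), np.nan)
    areas = np.full((n_frames, n), np.nan)
    status = np.full((n_frames, n), 1, dtype=np.int8)
    ses.ids, ses.xs, ses.ys = ids, xs, ys
    ses.status = status

    w_score = config.confidence_multipliers.get("score", 0.0)
    mismatch_run = 0
    discrepancy = False

    for f in range(ff, n_frames):
        sl = slice(det_start[f], det_start[f + 1])
        idx = np.arange(sl.start, sl.stop)
        sing = idx[~is_bundle[sl]]
        bund = idx[is_bundle[sl]]

        preds = np.stack([predict_position(t, dt, config, geom) for t in trk])

        # 1-2. one global capacity-constrained assignment: each single
        # detection offers one slot, each bundle detection offers
        # member_count slots (at point-to-box distance, slightly penalized
        # so an exact single match wins over blob membership). This lets a
        # tracklet parked near a blob be traded out to its own detection
        # whenever that lowers the total cost.
        gates = np.array(
            [
                config.gate_cm
                * (config.bundle_exit_gate_mult if t.in_bundle else 1.0)
                for t in trk
            ]
        )
        slot_det: list[int] = list(sing)
        slot_is_bundle = [False] * len(sing)
        for j in bund:
            cnt = int(members[j]) if np.isfinite(members[j]) else n
            slot_det.extend([j] * cnt)
            slot_is_bundle.extend([True] * cnt)
        matched: dict[int, int] = {}
        bundled_now: dict[int, int] = {}
        if slot_det:
            cost = np.full((n, len(slot_det)), _BIG)
            for s in range(n):
                for q, j in enumerate(slot_det):
                    if slot_is_bundle[q]:
                        d = _point_box_dist(preds[s], box[j])
                        if d <= gates[s]:
                            cost[s, q] = d + 0.5
                    else:
                        d = float(np.hypot(*(preds[s] - pos[j])))
                        if d <= gates[s]:
                            cost[s, q] = d * (
                                1.0 + w_score * (1.0 - score[j])
                            )
            ri, ci = linear_sum_assignment(cost)
            for s, q in zip(ri, ci):
                if cost[s, q] >= _BIG:
                    continue
                if slot_is_bundle[q]:
                    bundled_now[s] = slot_det[q]
                else:
                    matched[s] = slot_det[q]
        # 3. re-acquire: orphan detections adopt long-coasting tracklets
        orphans = [j for j in sing if j not in matched.values()]
        if orphans:
            lost = [
                s
                for s in range(n)
                if s not in matched
                and s not in bundled_now
                and trk[s].frames_since_seen >= config.reacquire_after_frames
            ]
            for j in orphans:
                if not lost:
                    break
                d = [float(np.hypot(*(preds[s] - pos[j]))) for s in lost]
                s = lost.pop(int(np.argmin(d)))
                matched[s] = j
                trk[s].vel_cm_s = np.zeros(2)
                trk[s].confirmed = False

        # 4. state updates
        for s, t in enumerate(trk):
            if s in matched:
                j = matched[s]
                gap = t.frames_since_seen + 1
                inst = (pos[j] - t.pos_cm) / (gap * dt)
                sp = float(np.hypot(*inst))
                if sp > config.max_speed_cm_s:
                    inst *= config.max_speed_cm_s / sp
                t.vel_cm_s = 0.7 * inst + 0.3 * t.vel_cm_s
                t.emit_pos = None
                t.last_box = None
                t.bundle_frames = 0
                d1 = float(np.hypot(*(pos[j] - t.pos_cm)))
                if d1 > config.gate_cm:
                    # discontinuous re-binding: identity no longer verified
                    t.confirmed = False
                elif t.in_bundle:
                    # emerging from a bundle: if another detection was nearly
                    # as close, the re-association was a guess
                    others = [
                        float(np.hypot(*(pos[q] - t.pos_cm)))
                        for q in idx
                        if q != j
                    ]
                    if others and min(others) - d1 < 3.0:
                        t.confirmed = False
                t.pos_cm = pos[j].copy()
                t.frames_since_seen = 0
                t.in_bundle = False
                t.status = 0
                t.area_px = float(area[j])
                if np.all(np.isfinite(head[j])):
                    t.head_offset_cm = head[j] - pos[j]
            elif s in bundled_now:
                # hold in box-relative coordinates: translate with the bundle
                # box, advance by the member's own damped residual velocity,
                # and confine to the box. A resting huddle freezes members at
                # their entry spots; a moving bundle (chase) carries its
                # members along preserving their relative order; a brief
                # crossing lets the faster animal pass through.
                j = bundled_now[s]
                if float(np.hypot(*t.vel_cm_s)) < 1.0:
                    # a resting member holds its own position: it does not
                    # teleport with a bundle passing over it, and its spot
                    # is the best claim on its re-emerging detection
                    held = t.pos_cm
                else:
                    # rigid component of the box motion: per axis, the
                    # same-sign minimum of the two edge displacements. A
                    # deforming box (one animal walking past a resting one)
                    # contributes nothing; a rigidly moving box (a chase)
                    # carries its members along.
                    delta = np.zeros(2)
                    if t.in_bundle and t.last_box is not None:
                        for ax in (0, 1):
                            d1 = box[j][ax] - t.last_box[ax]
                            d2 = box[j][ax + 2] - t.last_box[ax + 2]
                            if d1 * d2 > 0:
                                delta[ax] = d1 if abs(d1) < abs(d2) else d2
                    m = 0.5
                    ebox = np.array([box[j][0] - m, box[j][1] - m,
                                     box[j][2] + m, box[j][3] + m])
                    held = _clip_to_box(t.pos_cm + delta + t.vel_cm_s * dt, ebox)
                t.pos_cm = held
                # a stationary blob means its members stopped: shed stale
                # velocity quickly, otherwise keep motion through the blob
                if t.last_box is not None:
                    dc = math.hypot(
                        (box[j][0] + box[j][2] - t.last_box[0] - t.last_box[2]) / 2,
                        (box[j][1] + box[j][3] - t.last_box[1] - t.last_box[3]) / 2,
                    )
                    blob_static = dc / dt < 3.0  # blob speed below ~3 cm/s
                else:
                    blob_static = False
                t.vel_cm_s = t.vel_cm_s * (
                    0.7 if blob_static else config.bundle_vel_damping
                )
                t.last_box = box[j].copy()
                t.frames_since_seen = 0
                t.in_bundle = True
                t.bundle_frames += 1
                # reported position: held offset decayed toward the blob
                # centroid (the held hypothesis keeps full sharpness for
                # re-association on dissolution)
                c = np.array(
                    [(box[j][0] + box[j][2]) / 2, (box[j][1] + box[j][3]) / 2]
                )
                lam = config.bundle_offset_decay**t.bundle_frames
                off = (held - c) * lam
                # below ~1 cm the within-blob placement carries no real
                # information: report the blob centroid itself
                t.emit_pos = c + off if float(np.hypot(*off)) >= 1.0 else c.copy()
                t.status = 2
                t.area_px = float(area[j])
            else:
                t.pos_cm = preds[s]
                t.vel_cm_s = t.vel_cm_s * config.vel_damping
                t.frames_since_seen += 1
                t.in_bundle = False
                t.status = 1
                # keep the reported position continuous through brief
                # bundle-detection dropouts (emit_pos persists until the
                # next confirmed single detection)

        # 5. tag observations
        if tag_start is not None:
            for j in range(tag_start[f], tag_start[f + 1]):
                ses.apply_tag_observation(
                    f, int(tag_ids[j]), tag_pos[j], float(tag_scores[j])
                )

        # 6. roster discrepancy bookkeeping
        cap = len(sing) + (int(np.nansum(members[bund])) if len(bund) else 0)
        if cap != n:
            mismatch_run += 1
            if mismatch_run > 30 * fps:
                discrepancy = True
        else:
            mismatch_run = 0

        # 7. emit
        for s, t in enumerate(trk):
            ids[f, s] = t.current_id
            out_p = t.emit_pos if t.emit_pos is not None else t.pos_cm
            xs[f, s], ys[f, s] = out_p
            status[f, s] = t.status
            areas[f, s] = t.area_px
            if t.head_offset_cm is not None and t.status == 0:
                h = t.pos_cm + t.head_offset_cm
                hxs[f, s], hys[f, s] = h
                hds[f, s] = math.degrees(
                    math.atan2(t.head_offset_cm[1], t.head_offset_cm[0])
                )

    # frames before the first detection: hold initial state
    for f in range(0, ff):
        ids[f] = ids[ff]
        xs[f], ys[f] = xs[ff], ys[ff]

    out = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), n),
            "mouse_id": ids.ravel(),
            "x_cm": xs.ravel(),
            "y_cm": ys.ravel(),
            "head_x_cm": hxs.ravel(),
            "head_y_cm": hys.ravel(),
            "head_dir_deg": hds.ravel(),
            "area_px": areas.ravel(),
            "status": STATUS_NAMES[status.ravel()],
        }
    )
    out = out.sort_values(["frame", "mouse_id"], kind="stable").reset_index(drop=True)
    ledger = [
        PendingIdentityEvidence(k[0], k[1], v[0], v[1])
        for k, v in ses.ledger.items()
    ]
    return TrackResult(
        trajectory=out,
        relabel_count=ses.relabel_count,
        discrepancy_flag=discrepancy,
        ledger=ledger,
    )
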