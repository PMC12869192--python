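"""Accuracy bookkeeping: box overlap, behavior-event confusion with the
specificity = 1 - FP-rate / sensitivity = 1 - FN-rate convention, per-mouse
identity accuracy against ground truth, and a state-based ground-truth
metric panel for end-to-end consistency checks.

The FP rate is the share of predicted-event frames that are false
(precision-style denominator: when the tracker logs an event, how often is
it real); a conventional TN-based specificity is emitted alongside for
transparency. The overlap denominator is the union area by default
(intersection-over-union) and can be switched to the ground-truth area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CageGeometry, classify_zones_arrays
from .metrics import (
    FrameFeatures,
    MetricConfig,
    METRIC_NAMES,
    _kinematics,
    bin_masks,
    aggression_metrics,
    climbing_metrics,
    consumption_metrics,
    occupancy_metrics,
    rearing_metrics,
    sleep_metrics,
    social_distance,
    summarize_movement,
)


@dataclass
class OverlapStats:
    mean_overlap_pct: float
    misid_rate_pct: float
    n_frames: int


@dataclass
class EventConfusion:
    tp_frames: int
    fp_frames: int
    fn_frames: int
    tn_frames: int

    @property
    def fp_rate(self) -> float:
        d = self.tp_frames + self.fp_frames
        return self.fp_frames / d if d else 0.0

    @property
    def fn_rate(self) -> float:
        d = self.tp_frames + self.fn_frames
        return self.fn_frames / d if d else 0.0

    @property
    def specificity_pct(self) -> float:
        return 100.0 * (1.0 - self.fp_rate)

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * (1.0 - self.fn_rate)

    @property
    def specificity_tn_pct(self) -> float:
        """Conventional TN-based specificity, reported for transparency."""
        d = self.tn_frames + self.fp_frames
        return 100.0 * self.tn_frames / d if d else 100.0


def box_overlap(a, b, denominator: str = "union") -> float:
    """Shared area between two boxes (x1, y1, x2, y2), in percent."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    area_a = (ax2 - ax1) * (ay2 - ay1)
    area_b = (bx2 - bx1) * (by2 - by1)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("boxes must have positive area")
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    denom = area_a + area_b - inter if denominator == "union" else area_b
    return 100.0 * inter / denom


def bbox_accuracy(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    threshold_pct: float = 75.0,
    denominator: str = "union",
) -> OverlapStats:
    """Mean overlap and mis-identification rate over (frame, mouse) pairs.

    Both tables need columns frame, mouse_id, x1, y1, x2, y2. Ground-truth
    pairs with no matching prediction contribute overlap 0 and count as
    mis-identified.
    """
    cols = ["frame", "mouse_id", "x1", "y1", "x2", "y2"]
    for name, df in (("pred", pred), ("truth", truth)):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    if not set(truth["frame"]).intersection(pred["frame"]):
        raise ValueError("prediction and truth share no frames")
    m = truth.merge(pred, on=["frame", "mouse_id"], how="left",
                    suffixes=("_t", "_p"))
    overlaps = np.zeros(len(m))
    for i, row in enumerate(m.itertuples(index=False)):
        if np.isfinite(row.x1_p):
            overlaps[i] = box_overlap(
                (row.x1_p, row.y1_p, row.x2_p, row.y2_p),
                (row.x1_t, row.y1_t, row.x2_t, row.y2_t),
                denominator,
            )
    return OverlapStats(
        mean_overlap_pct=float(np.mean(overlaps)),
        misid_rate_pct=float(100.0 * np.mean(overlaps < threshold_pct)),
        n_frames=len(m),
    )


def event_rates(pred_flags, truth_flags) -> EventConfusion:
    """Frame-level confusion for one behavior from aligned flag vectors."""
    p = np.asarray(pred_flags, dtype=bool)
    t = np.asarray(truth_flags, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("flag vectors differ in length")
    return EventConfusion(
        tp_frames=int(np.sum(p & t)),
        fp_frames=int(np.sum(p & ~t)),
        fn_frames=int(np.sum(~p & t)),
        tn_frames=int(np.sum(~p & ~t)),
    )


def identity_accuracy(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    match_radius_cm: float = 4.0,
) -> tuple[dict[int, float], float]:
    """Percent of frames with correct identity, per mouse, plus the
    unweighted mean.

    A frame is correct for mouse ``m`` when the predicted row nearest to
    the true position of ``m`` (within the match radius) carries id ``m``;
    coincident predicted rows tie in favor of the correct id.
    """
    ids = np.sort(truth["mouse_id"].unique())
    if set(ids) != set(pred["mouse_id"].unique()):
        raise ValueError("prediction and truth rosters differ")
    n = len(ids)

    def grid(df, col):
        d = df.sort_values(["frame", "mouse_id"], kind="stable")
        return d[col].to_numpy(dtype=float).reshape(-1, n)

    common = np.intersect1d(truth["frame"].unique(), pred["frame"].unique())
    t = truth[truth["frame"].isin(common)]
    p = pred[pred["frame"].isin(common)]
    tx, ty = grid(t, "x_cm"), grid(t, "y_cm")
    px, py = grid(p, "x_cm"), grid(p, "y_cm")
    # pred columns are sorted by mouse_id, so column j carries id ids[j]
    d = np.sqrt(
        (tx[:, :, None] - px[:, None, :]) ** 2
        + (ty[:, :, None] - py[:, None, :]) ** 2
    )  # (frames, truth mouse, predicted id)
    d_min = d.min(axis=2)
    d_self = d[:, np.arange(n), np.arange(n)]
    correct = (d_self <= match_radius_cm) & (d_self <= d_min + 1e-9)
    per_mouse = {
        int(ids[j]): float(100.0 * correct[:, j].mean()) for j in range(n)
    }
    return per_mouse, float(np.mean(list(per_mouse.values())))


# ---------------------------------------------------------------------------
# state-based ground-truth panel


def panel_from_truth(
    truth: pd.DataFrame,
    geom: CageGeometry,
    config: MetricConfig,
    session_start_s: float = 8 * 3600.0,
    bins=("session",),
) -> pd.DataFrame:
    """The 21-metric panel derived from simulator ground truth.

    Behavior flags come from the annotated state labels (not from the
    geometric inference rules) and kinematics from the raw true positions,
    giving an independent reference for end-to-end consistency checks of
    the metric engine.
    """
    from .simulate import _truth_grids  # local import to avoid cycle

    ids, X, Y, HD, AREA, STATE = _truth_grids(truth)
    n_frames, n = X.shape
    speed, accel, angular, move_dir, moving, _ = _kinematics(X, Y, config.fps, config)
    inactive = STATE == "REST_SLEEP"
    z = classify_zones_arrays(np.stack([X.ravel(), Y.ravel()], axis=1), geom)
    shape = (n_frames, n)
    ff = FrameFeatures(
        mouse_ids=ids, fps=config.fps, x=X, y=Y,
        head_x=X.copy(), head_y=Y.copy(), area=AREA,
        speed=speed, accel=accel, angular_vel=angular, move_dir_deg=move_dir,
        moving=moving & ~inactive, inactive=inactive,
        center=z["center"].reshape(shape), front=z["front"].reshape(shape),
        corner=z["corner"].reshape(shape),
        enrichment=z["enrichment"].reshape(shape),
        wall_band=z["wall_band_side"].reshape(shape),
        eating=STATE == "EAT", drinking=STATE == "DRINK",
        rearing=STATE == "REAR", climbing=STATE == "CLIMB",
        aggression=STATE == "AGGRESSION",
    )
    rows = []
    for bin_id, phase, mask in bin_masks(
        n_frames, config.fps, session_start_s, config, bins
    ):
        for j, mid in enumerate(ids):
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
                rows.append((int(mid), bin_id, phase, name, vals.get(name, np.nan)))
    return pd.DataFrame(rows, columns=["mouse_id", "bin_id", "phase", "metric",
                                       "value"])
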