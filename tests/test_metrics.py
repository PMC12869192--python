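import numpy as np
import pandas as pd
import pytest

from homecage.geometry import CageGeometry
from homecage.metrics import (
    MetricConfig,
    METRIC_NAMES,
    FrameFeatures,
    aggregate_panel,
    aggression_metrics,
    compute_frame_features,
    consumption_metrics,
    filter_runs,
    flag_runs,
    merge_runs,
    occupancy_metrics,
    rearing_metrics,
    sleep_metrics,
    smooth_trajectories,
    social_distance,
    summarize_movement,
)

GEOM = CageGeometry()
CFG = MetricConfig()


def make_traj(xy_by_mouse, head=None, area=5400.0, hd=None):
    rows = []
    for mid, xy in xy_by_mouse.items():
        for f, (x, y) in enumerate(xy):
            hx, hy = (head[mid][f] if head else (np.nan, np.nan))
            rows.append(
                dict(frame=f, mouse_id=mid, x_cm=x, y_cm=y, head_x_cm=hx,
                     head_y_cm=hy,
                     head_dir_deg=(hd[mid][f] if hd else np.nan),
                     area_px=(area[mid][f] if isinstance(area, dict) else area),
                     status="detected")
            )
    return pd.DataFrame(rows).sort_values(["frame", "mouse_id"]).reset_index(drop=True)


def blank_features(n_frames, n_mice=1, fps=10.0, **overrides):
    shape = (n_frames, n_mice)
    base = dict(
        mouse_ids=np.arange(1, n_mice + 1), fps=fps,
        x=np.full(shape, 10.0), y=np.full(shape, 9.0),
        head_x=np.full(shape, np.nan), head_y=np.full(shape, np.nan),
        area=np.full(shape, 5400.0),
        speed=np.zeros(shape), accel=np.zeros(shape),
        angular_vel=np.zeros(shape), move_dir_deg=np.full(shape, np.nan),
        moving=np.zeros(shape, dtype=bool), inactive=np.zeros(shape, dtype=bool),
        center=np.zeros(shape, dtype=bool), front=np.zeros(shape, dtype=bool),
        corner=np.zeros(shape, dtype=bool), enrichment=np.zeros(shape, dtype=bool),
        wall_band=np.full(shape, "none", dtype=object),
        eating=np.zeros(shape, dtype=bool), drinking=np.zeros(shape, dtype=bool),
        rearing=np.zeros(shape, dtype=bool), climbing=np.zeros(shape, dtype=bool),
        aggression=np.zeros(shape, dtype=bool),
    )
    base.update(overrides)
    return FrameFeatures(**base)


# ---------------------------------------------------------------------------
# smoothing and kinematics


def test_smoothing_constant_unchanged():
    traj = make_traj({1: [(10.0, 9.0)] * 50})
    sm = smooth_trajectories(traj, CFG)
    assert np.allclose(sm["x_cm"], 10.0) and np.allclose(sm["y_cm"], 9.0)


def test_smoothing_removes_single_frame_spike():
    xy = [(10.0, 9.0)] * 50
    xy[25] = (20.0, 9.0)
    sm = smooth_trajectories(make_traj({1: xy}), CFG)
    assert np.allclose(sm["x_cm"], 10.0)


def test_smoothing_window_one_is_identity():
    xy = [(float(i), 9.0) for i in range(20)]
    traj = make_traj({1: xy})
    sm = smooth_trajectories(traj, MetricConfig(smooth_window_frames=1))
    pd.testing.assert_frame_equal(sm, traj)


def test_kinematics_straight_line():
    xy = [(5.0 + 0.2 * i, 9.0) for i in range(100)]  # 2 cm/s at 10 fps
    ff = compute_frame_features(make_traj({1: xy}),
                                GEOM, MetricConfig(smooth_window_frames=1))
    assert np.allclose(ff.speed[2:, 0], 2.0, atol=1e-9)
    assert np.allclose(ff.accel[2:, 0], 0.0, atol=1e-9)
    assert np.allclose(ff.angular_vel[3:, 0], 0.0, atol=1e-9)


def test_kinematics_quarter_turn_angular_velocity():
    # constant speed along a quarter circle over 1 s -> about 90 deg/s
    th = np.linspace(0, np.pi / 2, 11)
    xy = [(16 + 5 * np.cos(a), 9 + 5 * np.sin(a)) for a in th]
    ff = compute_frame_features(make_traj({1: xy}),
                                GEOM, MetricConfig(smooth_window_frames=1))
    assert np.allclose(np.abs(ff.angular_vel[3:, 0]), 90.0, atol=2.0)


def test_stationary_becomes_inactive():
    ff = compute_frame_features(make_traj({1: [(10.0, 9.0)] * 300}), GEOM, CFG)
    assert ff.inactive[:, 0].all()


# ---------------------------------------------------------------------------
# run-length utilities against naive oracles


def _naive_runs(flags):
    out, i = [], 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j < len(flags) and flags[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


@pytest.mark.parametrize("trial", range(20))
def test_run_utilities_match_naive_oracle(trial, rng):
    flags = rng.random(500) < 0.3
    assert flag_runs(flags) == _naive_runs(flags)
    min_f = int(rng.integers(1, 20))
    expect = np.zeros(len(flags), dtype=bool)
    for a, b in _naive_runs(flags):
        if b - a >= min_f:
            expect[a:b] = True
    assert np.array_equal(filter_runs(flags, min_f), expect)
    gap = int(rng.integers(1, 30))
    merged = merge_runs(_naive_runs(flags), gap)
    # naive merge
    naive = []
    for a, b in _naive_runs(flags):
        if naive and a - naive[-1][1] <= gap:
            naive[-1] = (naive[-1][0], b)
        else:
            naive.append((a, b))
    assert merged == naive


# ---------------------------------------------------------------------------
# movement summary and sleep


def test_top_one_percent_max_speed_exact():
    n = 1000
    ff = blank_features(n, speed=np.arange(1.0, n + 1.0).reshape(-1, 1))
    out = summarize_movement(ff, 0, np.ones(n, dtype=bool))
    assert out["max_speed_cm_s"] == pytest.approx(995.5)  # mean of top 10


def test_constant_speed_collapses_all_speed_metrics():
    n = 500
    v = 4.0
    ff = blank_features(n, speed=np.full((n, 1), v),
                        moving=np.ones((n, 1), dtype=bool))
    out = summarize_movement(ff, 0, np.ones(n, dtype=bool))
    assert out["avg_speed_cm_s"] == pytest.approx(v)
    assert out["avg_awake_speed_cm_s"] == pytest.approx(v)
    assert out["max_speed_cm_s"] == pytest.approx(v)
    assert out["distance_cm"] == pytest.approx(v * n / 10.0)


def test_fully_inactive_bin_leaves_awake_metrics_missing():
    n = 100
    ff = blank_features(n, inactive=np.ones((n, 1), dtype=bool))
    with pytest.warns(UserWarning):
        out = summarize_movement(ff, 0, np.ones(n, dtype=bool))
    assert out["avg_speed_cm_s"] == 0.0
    assert np.isnan(out["avg_awake_speed_cm_s"])
    assert np.isnan(out["max_speed_cm_s"])


def test_sleep_two_minute_boundary_exact():
    for run, bouts in [(1200, 1.0), (1199, 0.0)]:
        inact = np.zeros((3000, 1), dtype=bool)
        inact[100:100 + run] = True
        ff = blank_features(3000, inactive=inact)
        out = sleep_metrics(ff, 0, np.ones(3000, dtype=bool))
        assert out["sleep_bouts"] == bouts


def test_alternating_sleep_pattern():
    # 3 min inactive / 1 min active for one hour: 15 bouts, 75% sleep
    frames = 36000
    inact = np.zeros((frames, 1), dtype=bool)
    for start in range(0, frames, 2400):
        inact[start:start + 1800] = True
    ff = blank_features(frames, inactive=inact)
    out = sleep_metrics(ff, 0, np.ones(frames, dtype=bool))
    assert out["sleep_bouts"] == 15.0
    assert out["sleep_time_pct"] == pytest.approx(75.0)


# ---------------------------------------------------------------------------
# behavior rules


def test_occupancy_counting():
    # half the bin at exact cage center, half in a corner
    xy = [(16.0, 9.0)] * 50 + [(1.0, 1.0)] * 50
    ff = compute_frame_features(make_traj({1: xy}),
                                GEOM, MetricConfig(smooth_window_frames=1))
    out = occupancy_metrics(ff, 0, np.ones(100, dtype=bool))
    assert out["center_pct"] == pytest.approx(50.0)
    assert out["corner_pct"] == pytest.approx(50.0)
    assert out["front_pct"] == pytest.approx(100.0)


def test_eating_requires_facing_the_hopper():
    n = 100
    hopper_head = [(16.0, 1.2)] * n
    body = [(16.0, 3.5)] * n
    facing = make_traj({1: body}, head={1: hopper_head},
                       hd={1: [-90.0] * n})  # toward the front wall
    away = make_traj({1: body}, head={1: hopper_head}, hd={1: [90.0] * n})
    cfg1 = MetricConfig(smooth_window_frames=1)
    ff1 = compute_frame_features(facing, GEOM, cfg1)
    ff2 = compute_frame_features(away, GEOM, cfg1)
    assert consumption_metrics(ff1, 0, np.ones(n, bool))["eating_pct"] == 100.0
    assert consumption_metrics(ff2, 0, np.ones(n, bool))["eating_pct"] == 0.0


def test_consumption_dwell_threshold():
    n = 100
    head = [(np.nan, np.nan)] * n
    for f in range(50, 55):  # 0.5 s dwell < 1 s minimum
        head[f] = (16.0, 1.2)
    body = [(16.0, 3.5)] * n
    traj = make_traj({1: body}, head={1: head}, hd={1: [-90.0] * n})
    ff = compute_frame_features(traj, GEOM, MetricConfig(smooth_window_frames=1))
    assert consumption_metrics(ff, 0, np.ones(n, bool))["eating_pct"] == 0.0


def test_missing_head_data_yields_missing_not_zero():
    ff = blank_features(50)
    with pytest.warns(UserWarning):
        out = consumption_metrics(ff, 0, np.ones(50, bool))
    assert np.isnan(out["eating_pct"]) and np.isnan(out["drinking_pct"])


def test_rearing_rule_and_hopper_wall_exclusion():
    n = 60
    # 2 s in the left wall band with foreshortened area -> one event
    area = {1: [5400.0] * n}
    for f in range(20, 40):
        area[1][f] = 2500.0
    left = make_traj({1: [(1.0, 9.0)] * n}, area=area)
    cfg1 = MetricConfig(smooth_window_frames=1)
    ff = compute_frame_features(left, GEOM, cfg1)
    out = rearing_metrics(ff, 0, np.ones(n, bool))
    assert out["rearing_events"] == 1.0
    # same signature at the hopper (front) wall: excluded
    front = make_traj({1: [(16.0, 1.4)] * n}, area=area)
    ff2 = compute_frame_features(front, GEOM, cfg1)
    assert rearing_metrics(ff2, 0, np.ones(n, bool))["rearing_events"] == 0.0


def test_climbing_requires_upper_hopper():
    n = 60
    cfg1 = MetricConfig(smooth_window_frames=1)
    # session median area must reflect the unforeshortened majority
    area = {1: [5400.0] * 45 + [2500.0] * 15}
    upper = make_traj({1: [(16.0, 3.0)] * 45 + [(16.0, 0.5)] * 15}, area=area)
    ff = compute_frame_features(upper, GEOM, cfg1)
    out = ff.climbing[:, 0]
    assert out[45:].all() and not out[:45].any()
    lower = make_traj({1: [(16.0, 3.0)] * 45 + [(16.0, 1.8)] * 15}, area=area)
    ff2 = compute_frame_features(lower, GEOM, cfg1)
    assert not ff2.climbing[:, 0].any()


def _chase(n_pause_s=0.0, gap_between_bouts_s=0.0, bout_s=30.0, fps=10):
    """Two mice: B chases A at 4 cm, with optional mid-bout pause and a
    second bout after a gap."""
    frames = []
    t = 0.0

    def chase_block(dur):
        nonlocal t
        k = int(dur * fps)
        for i in range(k):
            x = 5.0 + ((t * 10.0) % 22.0)
            frames.append(((x, 9.0), (x - 4.0, 9.0)))
            t += 1.0 / fps

    def still_block(dur):
        nonlocal t
        k = int(dur * fps)
        for _ in range(k):
            frames.append(((20.0, 15.0), (5.0, 3.0)))
            t += 1.0 / fps

    chase_block(bout_s / 2)
    if n_pause_s:
        # pause in place, still close together
        k = int(n_pause_s * fps)
        last = frames[-1]
        frames.extend([last] * k)
        t += n_pause_s
    chase_block(bout_s / 2)
    if gap_between_bouts_s:
        still_block(gap_between_bouts_s)
        chase_block(bout_s)
    a = [f[0] for f in frames]
    b = [f[1] for f in frames]
    return make_traj({1: a, 2: b})


def test_chase_with_short_pause_is_one_event():
    traj = _chase(n_pause_s=3.0)
    ff = compute_frame_features(traj, GEOM, MetricConfig(smooth_window_frames=1))
    out = aggression_metrics(ff, 0, np.ones(ff.n_frames, bool), CFG)
    assert out["aggression_events"] == 1.0


def test_separated_clusters_are_two_events():
    traj = _chase(gap_between_bouts_s=600.0)
    ff = compute_frame_features(traj, GEOM, MetricConfig(smooth_window_frames=1))
    out = aggression_metrics(ff, 0, np.ones(ff.n_frames, bool), CFG)
    assert out["aggression_events"] == 2.0


def test_distant_mice_never_aggressive():
    traj = make_traj({1: [(5.0, 9.0)] * 100, 2: [(25.0, 9.0)] * 100})
    ff = compute_frame_features(traj, GEOM, MetricConfig(smooth_window_frames=1))
    out = aggression_metrics(ff, 0, np.ones(100, bool), CFG)
    assert out["aggression_events"] == 0.0
    assert out["aggression_time_pct"] == 0.0


def test_social_distance_pairs_and_triples():
    two = make_traj({1: [(10.0, 9.0)] * 10, 2: [(18.0, 9.0)] * 10})
    ff = compute_frame_features(two, GEOM, MetricConfig(smooth_window_frames=1))
    assert social_distance(ff, 0, np.ones(10, bool))["social_distance_cm"] == pytest.approx(8.0)
    three = make_traj({1: [(2.0, 9.0)] * 10, 2: [(5.0, 9.0)] * 10,
                       3: [(12.0, 9.0)] * 10})
    ff3 = compute_frame_features(three, GEOM, MetricConfig(smooth_window_frames=1))
    vals = [social_distance(ff3, j, np.ones(10, bool))["social_distance_cm"]
            for j in range(3)]
    assert vals == pytest.approx([3.0, 3.0, 7.0])


def test_single_mouse_social_distance_missing():
    ff = blank_features(10)
    with pytest.warns(UserWarning):
        out = social_distance(ff, 0, np.ones(10, bool))
    assert np.isnan(out["social_distance_cm"])


# ---------------------------------------------------------------------------
# panel assembly and binning


def test_panel_has_21_metrics_and_valid_ranges(small_session):
    from homecage.simulate import trajectory_from_truth

    cfg, out = small_session
    traj = trajectory_from_truth(out.truth)
    panel = aggregate_panel(traj, cfg.geom, MetricConfig(fps=cfg.fps))
    sess = panel[(panel.bin_id == "session") & (panel.phase == "all")]
    assert sorted(sess["metric"].unique()) == sorted(METRIC_NAMES)
    pct = sess[sess.metric.str.endswith("_pct")]["value"].dropna()
    assert ((pct >= 0) & (pct <= 100)).all()
    counts = sess[sess.metric.str.contains("events|bouts")]["value"].dropna()
    assert (counts >= 0).all() and np.allclose(counts, counts.round())
    # top-1% estimator dominates the awake mean
    wide = sess.pivot(index="mouse_id", columns="metric", values="value")
    ok = wide.dropna(subset=["max_speed_cm_s", "avg_awake_speed_cm_s"])
    assert (ok["max_speed_cm_s"] >= ok["avg_awake_speed_cm_s"] - 1e-9).all()


def test_two_day_session_emits_two_day_rows():
    fps = 0.1  # one frame per 10 s keeps a 48 h trajectory small
    frames = int(48 * 3600 * fps)
    xy = [(16.0, 9.0)] * frames
    traj = make_traj({1: xy})
    panel = aggregate_panel(traj, GEOM, MetricConfig(fps=fps))
    assert {"day0", "day1"}.issubset(set(panel["bin_id"]))
    phases = set(panel[panel.bin_id == "session"]["phase"])
    assert {"all", "light", "dark"}.issubset(phases)


def test_activity_only_in_dark_phase_shows_zero_light_distance():
    fps = 1.0
    frames = int(24 * 3600 * fps)
    xs = np.full(frames, 16.0)
    t = np.arange(frames) / fps
    clock = (8 * 3600 + t) % 86400
    dark = (clock < 8 * 3600) | (clock >= 20 * 3600)
    xs = 16.0 + np.where(dark, np.sin(t) * 5.0, 0.0)
    traj = make_traj({1: list(zip(xs, np.full(frames, 9.0)))})
    panel = aggregate_panel(traj, GEOM, MetricConfig(fps=fps),
                            bins=("light", "dark"))
    light = panel[(panel.phase == "light") & (panel.metric == "distance_cm")]
    dark_v = panel[(panel.phase == "dark") & (panel.metric == "distance_cm")]
    assert float(light["value"].iloc[0]) == pytest.approx(0.0, abs=1e-6)
    assert float(dark_v["value"].iloc[0]) > 100.0


def test_fixed_definitions_cannot_be_changed():
    with pytest.raises(ValueError):
        MetricConfig(sleep_min_s=60.0)
    with pytest.raises(ValueError):
        MetricConfig(top_fraction=0.05)
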