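# homecage

Identity-preserving multi-animal tracking and behavioral phenotyping for
group-housed mice, operating purely on detection streams.

Continuous home-cage monitoring of 2–5 co-housed mice from an overhead
camera yields, per video frame, a set of body/head bounding boxes — merged
into a single "bundle" detection whenever animals are in contact — plus
occasional sightings of numbered ear tags. `homecage` turns those streams
into:

- an **identity-resolved trajectory** for every declared animal in every
  frame (tracking-by-detection with damped constant-velocity prediction,
  Hungarian association under a distance gate, occlusion handling that
  freezes identities inside bundles, and conservative ear-tag error
  correction: identity switches require repeated high-confidence
  mismatching tag sightings and are applied retroactively back to the last
  mutual ambiguity of the two animals);
- the **21 home-cage health metrics** across 9 categories (acceleration,
  angular motion, average/awake-average/max movement speed, distance,
  aggression events and time, social distance, cage center/front/corner and
  enrichment-tube occupancy, climbing and rearing events and times, eating
  and drinking times, sleep bouts and sleep time), binned over 24 h windows
  and light/dark phases. Sleep is continuous inactivity of at least 2
  minutes; "max movement speed" is the mean of the top 1% of frame-wise
  speeds during active periods;
- a **Digital Bioage** composite: ordinary least squares mapping 8
  standardized behavioral features (time rearing, rearing events, average
  and max speed, acceleration, climbing events, distance, sleep time) onto
  chronological age in days;
- **validation statistics**: intersection-over-union box overlap and
  mis-identification rate (overlap < 75%), frame-level behavior confusion
  with specificity = 1 − FP rate and sensitivity = 1 − FN rate, and
  per-mouse identity accuracy;
- an **agent-based cage simulator** producing ground-truth tracks, degraded
  detections (bundles, misses, jitter) and tag sightings, so the entire
  pipeline is testable without any video data.

## Worked example

```python
from homecage import (SimConfig, simulate_session, Roster, track_session,
                      MetricConfig, aggregate_panel, identity_accuracy)

cfg = SimConfig(n_mice=4, duration_s=3600, seed=1)     # one simulated hour
sim = simulate_session(cfg)                            # truth + detections + tags
res = track_session(sim.detections, sim.tags,
                    Roster(frozenset([1, 2, 3, 4])),
                    cfg.cal, geom=cfg.geom, fps=cfg.fps)
per_mouse, mean = identity_accuracy(res.trajectory, sim.truth)
print({k: round(v, 1) for k, v in per_mouse.items()}, round(mean, 1))

# the inactivity threshold must sit above the localization noise floor
# (2 px box jitter at 15 px/cm puts frame-wise speed noise near 1.3 cm/s)
mcfg = MetricConfig(fps=cfg.fps, inactivity_speed_cm_s=2.0)
panel = aggregate_panel(res.trajectory, cfg.geom, mcfg)
sess = panel[(panel.bin_id == "session") & (panel.phase == "all")]
print(sess[(sess.mouse_id == 1) & sess.metric.isin(
    ["sleep_time_pct", "distance_cm", "aggression_events"])].round(2))
```

prints (seed 1):

```
{1: 80.3, 2: 74.5, 3: 77.5, 4: 80.8} 78.3
    mouse_id   bin_id phase             metric     value
5          1  session   all        distance_cm  12861.92
6          1  session   all  aggression_events     13.00
20         1  session   all     sleep_time_pct      7.53
```

The per-mouse numbers are the percentage of frames in which the row nearest
each animal's true position carries the right identity; `distance_cm` is
the hour's total path length and `sleep_time_pct` the share of the hour in
inactivity bouts of two minutes or more. On this noisy benchmark the
residual identity errors leak activity between animals (which is why the
per-animal sleep figure here is well below the simulated animal's true
value — see the methods note); on noiseless input the panel recovers the
ground-truth behavior program to within one percentage point per metric.
The same pipeline is available from the shell: `homecage simulate | track |
metrics | validate | bioage fit/predict | run-all`, each taking `--config`,
`--seed`, `--out`.

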