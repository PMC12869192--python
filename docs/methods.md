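# Methods

`homecage` is a detection-stream engine for group-housed mouse phenotyping:
it starts where a visual detector ends (per-frame bounding boxes and ear-tag
sightings) and produces identity-resolved trajectories, a 21-metric behavior
panel, a behavioral-aging composite, and validation statistics. This note
documents the models, the defaults and why they were chosen, the synthetic
data generator's assumptions, and known limitations.

## Coordinate model

The cage floor is a continuous-centimeter rectangle (default 32 × 18 cm, an
Allentown-style footprint; configurable) with the origin at the front-left
corner and y increasing toward the back wall. Pixel coordinates map to cm by
an axis-aligned affine calibration (`px_per_cm_x/y`, `origin_px`); lens
distortion is assumed corrected upstream by whatever produced the
detections. Zone definitions, all boundary-inclusive:

- **center**: at least `center_margin_cm` (default 2.0) from every wall;
- **corner**: inside a `corner_side_cm` square (default 3.0, ≈9 cm²) at any
  of the four corners; corner membership excludes center;
- **front**: the half of the floor nearer the front wall;
- **enrichment**: inside the tube rectangle dilated by `tube_halo_cm`
  ("on, in, or immediately around" the tube);
- **wall bands** (`wall_band_cm`, default 2.5): proximity bands along the
  three non-hopper walls, used by the rearing rule. By default the food
  hopper and water spout sit on the front wall.

## Tracker

Tracking-by-detection with a fixed, user-declared roster: exactly one row
per declared identity per frame, always. Detections beyond the roster are
ignored; missing detections are coasted.

**Prediction.** Damped constant velocity: `p + v·λ^k·dt` with per-frame
damping λ (default 0.9) and k the frames since the last detection, clamped
to the floor.

**Association.** One global minimum-cost assignment per frame
(`scipy.optimize.linear_sum_assignment`) over *capacity slots*: each single
detection is one slot; each merged "bundle" detection contributes
`member_count` slots at point-to-box distance (slightly penalized so an
exact single match beats blob membership). Pairs beyond the gate
(`gate_cm`, default 6; doubled for tracklets emerging from a bundle, whose
positional uncertainty is box-sized) are forbidden. Detection scores
mildly inflate association cost via a configurable multiplier. A
long-coasting tracklet may re-acquire an orphan detection (one no tracklet
claims); such discontinuous bindings are marked unverified.

**Bundles.** While animals share a merged detection their identities are
frozen. Each member is held at its own prediction, confined to the bundle
box: a resting member (negligible velocity) holds its exact position and is
never dragged by a box passing over it; a moving member keeps its
(gently damped) velocity plus the box's rigid translation — computed per
axis as the same-sign minimum of the two edge displacements, so a deforming
box (one animal walking past a resting one) contributes nothing while a
rigidly moving box (a chase) carries its members along. A stationary box
sheds members' stale velocity quickly (everyone inside has stopped). On
dissolution, emerging detections re-bind to members by the same global
minimum-cost assignment from the held positions; near-tie re-associations
are marked unverified.

The *reported* position of a bundled animal decays toward the blob centroid
(per-frame factor 0.93) and collapses onto it exactly once the residual
offset falls below 1 cm: the within-blob placement is genuinely unknown
after a long occlusion, and the output says so. The sharper internal
hypothesis is kept for re-association only. Reported positions stay
continuous through brief bundle-detection dropouts.

**Ear-tag identity maintenance.** A sighting binds to the nearest
non-bundled tracklet within the gate, measured to the head when known (tags
sit on ears). A matching sighting confirms the identity; a mismatching
high-confidence sighting (score ≥ 0.8) is evidence that the sighted tag
belongs on that tracklet. Switches between two *confirmed* identities are
deferred until `switch_evidence_k` (default 2) mismatching sightings
support the same exchange — evidence from either animal of a swapped pair
is pooled, and evidence survives unrelated switches. An identity that is
still provisional (never tag-confirmed: the arbitrary initial binding, a
re-acquired tracklet, an ambiguous bundle exit, or the silent recipient of
a previous swap) is instead re-bound immediately by its first
high-confidence sighting, because that sighting completes the tag-based
assignment rather than overturning corroborated evidence.

**Retroactive repair.** A committed switch exchanges the two id values
backwards through the output, to the most recent frame at which the two
tracklets could actually have swapped: within the gate of each other, not
both cleanly detected, and at least one moving (two resting animals cannot
exchange bodies). The search starts from the first mismatching sighting,
is floored at the later of the two ids' last confirmed sightings and at the
retro horizon (default 300 s), and value-based rewriting keeps the history
consistent across overlapping switches. Identity changes only ever
originate from tag evidence: with the tag stream withheld the tracker
performs zero relabels.

## The 21 metrics

Trajectories are first smoothed with a centered moving median
(`smooth_window_frames`, default 5; shrunken at the edges). Frame
kinematics: speed `‖Δp‖·fps`; acceleration as the finite difference of
speed; angular velocity as the heading change of the displacement vector,
defined only while the displacement exceeds the movement threshold
(sub-threshold displacements are localization noise, not turning).

**Inactivity and sleep.** A frame is *moving* if speed exceeds
`inactivity_speed_cm_s` (default 0.5 — set it above your localization noise
floor). A frame is *inactive* when the moving fraction in a centered
`inactivity_smooth_s` window (default 10 s) is below 10%; inactivity is
then extended over each contiguous still period whose core passes the
windowed test, so bout boundaries land on the actual stillness edges and a
brief jostle from a cage mate does not split a rest bout. A **sleep bout**
is a maximal inactive run of at least 120 s (fixed by definition); sleep
time is the percentage of bin time inside such runs. Boundary behavior is
exact: a 1200-frame run at 10 fps is one bout, 1199 frames is none.

**Movement panel.** Average speed includes inactivity; awake average
excludes it; **max movement speed** is the mean of the top 1% (fixed) of
frame-wise speeds over the bin's active frames, which suppresses
single-frame spikes; acceleration and angular motion average their absolute
values over moving frames; distance is the summed path length.

**Consumption.** A frame is *eating* when the head centroid lies in the
hopper rectangle and the head direction points within `head_cone_deg`
(default 60°) of it; *drinking* analogously at the spout; the nearer
fixture wins a tie; runs must last `dwell_min_s` (default 1 s). Missing
head data yields missing values, never zeros.

**Rearing and climbing** use body-area foreshortening as the overhead
posture proxy: a frame is rearing when the animal is in a non-hopper wall
band, its box area is below `rear_area_ratio` (default 0.6) of its own
session-median area, and it is not inside the tube; climbing when the
centroid is in the upper hopper rectangle with the same area signature
(climbing wins over rearing). Runs of ≥0.5 s are events.

**Aggression.** A frame-level pair flag: centroid distance below
`aggr_proximity_cm` (5 cm) and either a directed chase (follower speed
above 8 cm/s, heading within the cone of the other animal) or mutual fast
turning (both above 180°/s) in near contact (`aggr_contact_cm`, 3 cm — a
centroid-distance stand-in for box overlap, since the trajectory table
carries no boxes). Flagged intervals separated by gaps of at most
`aggr_merge_gap_s` (5 s, the "few second pause") merge into one bout; a
bout must contain at least `aggr_min_bout_s` (5 s) of genuinely flagged
time — the minimum applies to flagged time rather than merged span so that
sparse incidental flags strung together by the merge gap do not count as
events. Each bout counts once per participant; aggression time is the
share of bin frames inside bouts.

**Social distance** is the mean over the bin of each animal's distance to
its nearest cage mate.

**Binning.** Metrics are computed per animal for the whole session, per
24 h window (when the session exceeds one day), and for the light and dark
phases of a 12 h cycle (light 08:00–20:00 by default), with the session's
wall-clock anchor supplied by configuration. A bout straddling a bin edge
contributes its frames to each bin but is counted once, in the bin holding
its start.

## Digital Bioage

Ordinary least squares of chronological age (days) on eight standardized
behavioral features (time rearing, rearing events, average and max speed,
acceleration, climbing events, distance, sleep time), each aggregated over
at least 48 h. Standardization parameters are stored in the model, making
predictions invariant to the units of raw inputs; constant features and
rank deficiency raise named errors; fits require at least 10 animals.
On a noiseless cohort whose ages are an exact affine function of the
features, the generating weights are recovered to 1e-8 and R² = 1. The
synthetic aging cohort draws ages uniformly from 113–933 days and gives
each feature an age trend plus independent noise scaled so the best
achievable linear R² equals a chosen value (0.9 by default); activity-type
features decline with age and sleep time rises. This is a feasibility
construct, not a claim about real aging trajectories.

## Validation statistics

Box overlap is intersection-over-union by default (the denominator is
configurable to the ground-truth area, since "shared area" admits both
readings); the mis-identification rate is the share of (frame, animal)
pairs with overlap below 75%, with missing predictions counting as zero
overlap. Behavior confusion is frame-level: the FP rate is the share of
predicted-event frames that are false (precision-style — chosen because it
matches the reading "when an event is logged, it is usually real"), the FN
rate the share of true-event frames missed; specificity = 1 − FP rate and
sensitivity = 1 − FN rate, with a conventional TN-based specificity
reported alongside. Identity accuracy is the percentage of frames, per
animal, in which the predicted row nearest the animal's true position
(within 4 cm) carries its id; exactly coincident rows tie in favor of the
correct id.

## The simulator

A semi-Markov state machine per animal over eight behavior states
(locomotion, rest/sleep, eating, drinking, rearing, climbing, tube use,
aggression), with uniform dwell sampling and configurable next-state
weights (dark-phase activity boosted by `diurnal_gain`). Locomotion is a
reflected correlated random walk with persistent segment speeds (3–12 cm/s,
heading noise 0.15 rad/frame). Goal-directed states are preceded by a
directed walk recorded as locomotion, and the animal settles exactly onto a
placement satisfying the corresponding metric rule (head in the hopper
facing it, body in the upper hopper rectangle with foreshortened area,
wall band, tube interior, or a dispersed resting site away from the feeder
wall). Animals wander briefly before settling to rest and after waking.
Aggression is a coordinated pursuit: the chaser trails the evader at
~4.5 cm (inside the 5 cm proximity rule but outside the 4 cm merge
threshold: detector-level merging corresponds to contact, not to a trailing
chase) for 20 s–5 min. Soft body exclusion (2.5 cm) keeps animals from
occupying the same point.

Degradation to detections: animals with pairwise centroid distance below
`bundle_dist_cm` (4 cm) merge into one bundle detection carrying the union
box and the member count; every detection is dropped independently with
`miss_prob`; box corners receive Gaussian pixel jitter. Ear-tag sightings
follow an exponential-gap process (mean `tag_mean_interval_s`, 7.5 s),
suppressed while the animal sleeps or is inside a bundle, positioned at the
head. Motion, detection noise and tag sightings draw from separate named
substreams of one seed, so each can be varied independently and a given
configuration is bit-reproducible.

What the simulator does **not** emulate: appearance (no pixel data, so no
re-identification signal), posture beyond a single foreshortening ratio,
burrowing or disappearance from view, litter/enrichment physics, and real
occlusion statistics — bundle frequency and duration emerge from the
movement model rather than from measured contact data. Passing tests
therefore demonstrate the correctness of the pipeline's logic under a
specified behavioral program, not performance on real video.

## Problem sizes and verification

The identity benchmark is 4 animals for 60 simulated minutes at 10 fps over
ten seeds (~1.4 M detection rows per run of `scripts/acceptance.py`); the
metric-recovery check uses a 3-animal hour without detector noise or
merging (isolating the geometric inference rules from contact mechanics);
bout-extraction and assignment checks run against brute-force oracles
(exhaustive permutation enumeration, naive run-length scans) on thousands
of randomized instances.

## Known limitations

- **Occlusion resolution is centroid-only.** Through a merged detection the
  tracker has motion continuity and the box geometry, nothing else. Head-on
  "bounce" encounters, order reversals inside long chases, and scrambles
  frozen into sleep huddles are intrinsically ambiguous at this level; tag
  sightings repair identities with a latency set by the sighting cadence
  and the two-sighting evidence rule. Under the default benchmark's contact
  statistics (roughly a fifth to a third of animal-time within 4 cm of a
  cage mate) per-animal identity accuracy reaches the mid-70s percent —
  substantially below what a pixel-level tracker achieves, because error
  creation at ambiguous dissolutions and tag-repair latency are of the same
  order. Identity errors leak behavior between animals, so per-animal
  metrics from noisy tracked sessions inherit this error; metric logic
  itself recovers a noiseless behavioral program to within one percentage
  point per metric.
- **Thresholds are operational definitions.** Inactivity (0.5 cm/s, 10 s
  window), the posture ratio (0.6), the aggression rule and its 5 s
  minimum flagged time, and the 60° interaction cone are declared defaults
  for unpublished quantities, not reconstructions; all are configurable.
  The 2-minute sleep rule and the top-1% speed definition are fixed.
- **Noise floors matter.** The movement threshold and the angular-velocity
  definition assume localization noise below the inactivity threshold;
  with coarse calibrations or heavy jitter, raise `inactivity_speed_cm_s`
  (and rely on the median smoother) accordingly.
- The Digital Bioage is a feasibility composite: nothing here validates it
  as a biomarker.
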