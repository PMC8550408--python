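# Methods

`blockreg` models a 3D docking experiment in which a subject registers a
movable cuboid ("tissue block") to a fixed target cuboid inside a reference
kidney, across three interface setups: a 2D desktop application (kidney
displayed 113 mm tall) and two room-scale VR variants (kidney 590 mm tall).
The package covers four stages: stimulus generation, telemetry scoring,
plateau detection, and cohort statistics, plus a synthetic cohort simulator
that exercises the whole pipeline.

## Stimulus schedule

A session is 45 tasks: 1 tutorial, 14 ramp-up, 30 plateau. Difficulty is a
triple (distance between start and target centroid, block edge length,
angular difference between start and target orientation), with all lengths
expressed as fractions of the kidney height so the schedule is identical
across display scales. Ramp-up task *i* sits at interpolation fraction
t = i/14 of a clamped linear schedule

    lerp(a, b, t) = a            for t <= 0
                  = b            for t >= 1
                  = a + (b-a)t   otherwise

with endpoints distance 0.30 → 2.00, size 0.20 → 0.05, and the target
orientation moving by spherical interpolation (slerp) from identity to the
Euler end rotation (0, 270, 180)°, which lies 180° from identity. Because
slerp traverses the geodesic at constant speed, the scalar angular
difficulty is linear in t (property-tested), so the angle schedule is
equivalently lerp(0°, 180°, t). Every plateau task uses the schedule
midpoints — distance 1.15, size 0.125 — at the maximum angular difference;
the midpoints are exact because the mean of the 15 evenly spaced ramp values
(tutorial included) equals the endpoint average.

Ramp-up tasks alternate audio prompts (odd → speed, even → accuracy);
the tutorial has none and all plateau tasks are performed for speed.

Choices the protocol text leaves open: the start block is displaced from
the target along +x by default (a seeded random unit direction is available;
only the magnitude enters any metric), and the target centroid sits at the
organ bounding-box center.

## Geometry conventions

Orientations are unit quaternions canonicalized to w ≥ 0; all metrics are
invariant under quaternion negation. Euler angles use the z-x-y composition
order of the engine the original interfaces were built in
(R = Ry(y)·Rx(x)·Rz(z) about fixed axes), stored in a right-handed y-up
frame; scalar metrics are handedness-invariant. The scalar angular
difference is 2·arccos(|q0·q1|) in degrees, in [0, 180]. Per-axis angular
deviations are wrapped differences of the z-x-y Euler decompositions,
wrapped to (−180, 180] with ties at ±180 resolved to +180, signed
tissue − target. When the x Euler angle is within 1e-4° of ±90 the y/z
split is not unique; the decomposition is flagged degenerate rather than
reporting an arbitrary split (the scalar angle is unaffected).

## Performance metrics

Per submitted task: **position accuracy** is the centroid distance in mm and
divided by the kidney height ("normalized"); **rotation accuracy** is the
scalar angular difference; **completion time** is the interval between
consecutive submissions, with the first task timed from the session's first
record. Over a set of placements, the per-axis **error** is the median
signed offset on each axis (even counts: mean of the two central order
statistics) and the **bias** is the Euclidean norm of that median vector.

## Plateau detection

Over the 30 identical plateau tasks, the relative deviation of task *i* is
|x_i − m_i| / m_i where m_i is the mean of a trailing window of up to 20
values ending at *i* (trailing, so late-task evaluation excludes the extreme
values typical of the phase start; truncated near the start). Scanning
backwards from the last task, the plateau extends while the relative
deviation does not exceed 1 — literally |x − mean| ≤ mean, a deliberately
loose criterion for positive series — and the plateau level is the mean over
the plateau tasks. If the last task itself deviates, no plateau was reached.
Onset is reported per subject; cohort summaries report the median level and
both the mean and median onset (a fractional "mean trials to plateau" is the
statistic usually quoted). Series must be strictly positive: the relative
deviation is undefined at mean 0.

## Synthetic cohort

The simulator is the package's own generative model, chosen as the simplest
forms exhibiting each phenomenon the analysis measures:

* completion time: exponential-approach learning curve
  T(n) = T_inf + (T0 − T_inf)·exp(−(n−1)/tau_T) over the 1-indexed
  session-wide task counter, times a prompt multiplier
  (rho_speed < 1 ≤ rho_accuracy, defaults 0.85/1.15) and lognormal noise
  exp(sigma_T·ε);
* placement: target position plus a fixed bias vector beta (kidney-height
  units) plus isotropic Gaussian noise sigma_p; the default 2D desktop
  profile injects beta = (−0.0114, 0, 0), the characteristic negative-x
  placement bias of a fixed-camera desktop interface;
* orientation: the target orientation perturbed about a uniformly random
  axis by |N(0, sigma_r(n))| degrees, sigma_r decaying from sigma_r0 to
  sigma_r_inf with its own timescale tau_r;
* within-task 10 Hz samples linearly interpolate (slerp for rotation) from
  start to final pose — no claim of human-motion realism, no camera/HMD
  poses, no reset events.

Default profiles are calibrated so the cohort reproduces the qualitative
orderings a real study of these interfaces shows (desktop ~3x slower,
rotationally less accurate, negative-x biased; VR satisfaction higher), with
asymptotes near the reported medians (22.6 s desktop, ~7 s VR). These
calibration values are demo defaults only; no acceptance check compares
simulator output against them, which would be circular. Per-subject seed
streams are spawned from a master seed, so cohorts are byte-reproducible.

What passing tests therefore show: the pipeline recovers parameters it
injects (bias, asymptote, prompt effects) at the stated sample sizes. What
they do not show: anything about real human motor behavior — heavy-tailed
times, within-task strategy changes, fatigue, or correlated per-axis errors
are all absent from the generator.

## Statistics

Pairwise group comparisons use the Kruskal–Wallis rank test (scipy,
tie-corrected, chi-square approximation) per pair with a Bonferroni-adjusted
level alpha / n_pairs; a fully tied pair is reported non-significant with a
warning. Correlations are Pearson r with two-sided p, optionally stratified
by prompt or setup; the task-complexity covariate is the ramp-up task index,
of which every difficulty parameter is a monotone function. Satisfaction
(Likert 1–5) is aggregated per setup by mean, with the combined mean taken
as the unweighted mean of per-setup means (groups of near-equal size make
this indistinguishable from the subject-weighted mean) and rounded to one
decimal for display. Missing responses are excluded with a logged count.

## Numerical choices and limitations

* lerp clamps outside [0, 1]; slerp falls back to normalized linear
  interpolation within 1e-12 of parallel quaternions.
* Plateau detection requires strictly positive series; scoring rejects
  non-positive completion times and duplicate submissions.
* Telemetry CSV stores positions to 6 decimals (mm), quaternions to 9,
  timestamps to 3; round trips are lossless at those precisions.
* Default problem sizes in the tests (cohorts of 2–10 subjects per setup,
  submit-only sessions for analysis paths) were chosen because every
  acceptance property is already stable there; the simulator scales to
  arbitrary cohort sizes with 10 Hz samples enabled.
* The pipeline analyzes submission rows only; the 10 Hz trajectories are
  carried for future trajectory work but never scored.
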