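# blockreg

A pipeline for 3D tissue-block registration experiments: generate
difficulty-graded docking-task protocols, score pose telemetry into
position/rotation accuracy and completion time, detect per-subject
performance plateaus, and compare interface setups statistically. It is
aimed at researchers evaluating registration interfaces (desktop vs VR) for
recording the spatial origin of tissue blocks relative to a reference organ,
and ships a synthetic cohort simulator so the whole analysis is testable
without human subjects.

## The model

A session is 45 tasks (1 tutorial, 14 ramp-up, 30 identical plateau tasks).
Ramp-up difficulty at fraction t = i/14 follows a clamped linear schedule
`lerp(a, b, t) = a + (b − a)t` (clamped at the endpoints): start–target
distance 0.30 → 2.00 kidney heights, block size 0.20 → 0.05, and target
orientation `slerp(identity, q_end, t)` with `q_end` the Euler rotation
(0, 270, 180)° in z-x-y order — 180° from identity, the maximum angular
difference. Plateau tasks sit at the schedule midpoints (distance 1.15,
size 0.125) at maximum angle. Normalizing by the displayed kidney height
(113 mm desktop, 590 mm VR) makes difficulty identical across setups.

Scored per submission: position accuracy `‖p_tissue − p_target‖` (mm and
normalized), rotation accuracy `2·arccos(|⟨q_tissue, q_target⟩|)` ∈ [0°, 180°],
and completion time between consecutive submissions. Over a set of
placements, per-axis *error* is the median signed offset and *bias* is the
Euclidean norm `d(p, q)` of the median-error vector `q` from the target `p`.
A performance plateau over the 30 identical tasks is the longest suffix in
which each task's relative deviation `|x_i − m_i| / m_i` from the trailing
20-task window mean `m_i` stays ≤ 1; its level is the mean over that suffix.

## Worked example

```python
import numpy as np
from dataclasses import replace
from blockreg import (CohortConfig, Setup, build_protocol, detect_plateau,
                      score_session, simulate_cohort, axis_error_summary,
                      cohort_plateau_summary)

cfg = CohortConfig(subjects_per_setup={s: 5 for s in Setup}, master_seed=7)
sessions = simulate_cohort(cfg, include_samples=False)
protocols = {s: build_protocol(replace(cfg.protocol_config, kidney_height_mm=h))
             for s, h in (("desktop_2d", 113.0), ("vr_tabletop", 590.0),
                          ("vr_standup", 590.0))}
for setup in ("desktop_2d", "vr_tabletop", "vr_standup"):
    results, errs = {}, []
    for sess in [s for s in sessions if s.setup.value == setup]:
        scored = score_session(sess, protocols[setup])
        plateau = [p for p in scored if p.phase.value == "plateau"]
        results[sess.subject_id] = detect_plateau(
            np.array([p.completion_time_s for p in plateau]))
        errs += [p.per_axis_position_error_norm.as_array() for p in plateau]
    summ = cohort_plateau_summary(results)
    es = axis_error_summary(np.array(errs))
    print(f"{setup:12s} plateau level {summ['median_level']:6.2f} s  "
          f"median x-error {es.median_error.x:+.4f}  bias {es.bias:.5f}")
```

prints

```
desktop_2d   plateau level  21.33 s  median x-error -0.0110  bias 0.01096
vr_tabletop  plateau level   6.14 s  median x-error +0.0024  bias 0.00355
vr_standup   plateau level   6.32 s  median x-error +0.0012  bias 0.00163
```

The simulated desktop cohort plateaus ~3x slower than both VR cohorts and
shows the characteristic negative-x placement bias (blocks placed slightly
toward −x, here ~1.1% of the kidney height) that the VR setups lack; the
recovered medians match the biases the simulator injected.

The same pipeline is available from the shell:

```
blockreg simulate --seed 7 --out telemetry/
blockreg score --telemetry-dir telemetry/ --out scored.csv
blockreg plateau --scored scored.csv --out plateau.json
blockreg stats --scored scored.csv --out stats.json
blockreg report --telemetry-dir telemetry/ --out report/
```

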