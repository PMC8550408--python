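"""Task scoring, per-axis error/bias summaries, and performance-plateau detection.

Position accuracy is the Euclidean distance between the tissue- and
target-block centroids at submission, reported both in mm and normalized by
the displayed kidney height so the 2D Desktop (113 mm) and VR (590 mm)
conditions are comparable.  Rotation accuracy is the scalar angular
difference in [0, 180] degrees.  Completion time is the interval between
consecutive submissions (the first task is timed from the session's first
record).

Per-axis *error* is the median signed placement offset (tissue - target) on
each axis over a set of placements; *bias* is the Euclidean norm of that
median vector, i.e. the distance d(p, q) from the target reference point p
(normalized to the origin) to the median-error point q.

A performance plateau over the 30 identical plateau-phase tasks is detected
with a trailing moving window of 20 tasks: for task i, the relative
deviation is |x_i - m_i| / m_i with m_i the mean of the (up to) 20 most
recent values ending at i.  Scanning backwards from the last task, the
plateau extends while the relative deviation does not exceed 1; its level is
the mean over the plateau tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    AxisDeviation,
    Vec3,
    angular_difference,
    centroid_distance,
    per_axis_angular_deviation,
)
from .schedule import Phase, Prompt, TaskSpec
from .telemetry import Submission, SubjectSession, extract_submissions

__all__ = [
    "TaskPerformance",
    "AxisErrorSummary",
    "PlateauResult",
    "score_task",
    "score_session",
    "performance_frame",
    "axis_error_summary",
    "detect_plateau",
    "cohort_plateau_summary",
]

#: Moving-window width (tasks) for plateau detection.
PLATEAU_WINDOW = 20


@dataclass(frozen=True)
class TaskPerformance:
    """All performance metrics for one scored task."""

    task_index: int
    phase: Phase
    prompt: Prompt
    position_accuracy_mm: float
    position_accuracy_norm: float
    rotation_accuracy_deg: float
    per_axis_position_error_mm: Vec3
    per_axis_position_error_norm: Vec3
    per_axis_angular_deviation: AxisDeviation
    completion_time_s: float


@dataclass(frozen=True)
class AxisErrorSummary:
    """Median signed per-axis error and its Euclidean norm (bias)."""

    median_error: Vec3
    bias: float
    n: int


@dataclass(frozen=True)
class PlateauResult:
    """Plateau onset and level of one performance variable for one subject."""

    variable: str
    window_width: int
    onset_task: int | None
    plateau_level: float | None
    reached: bool


def score_task(
    submission: Submission, spec: TaskSpec, previous_submit_time: float
) -> TaskPerformance:
    """Score one submission against its task specification."""
    if submission.phase is not spec.phase or submission.task_index != spec.index:
        raise ValueError(
            f"submission ({submission.phase.value}, {submission.task_index}) does not "
            f"match spec ({spec.phase.value}, {spec.index})"
        )
    completion = submission.submit_timestamp_s - previous_submit_time
    if completion <= 0:
        raise ValueError(
            f"non-positive completion time {completion} s for task "
            f"({spec.phase.value}, {spec.index})"
        )
    tissue, target = submission.tissue_pose, submission.target_pose
    dist_mm = centroid_distance(tissue.position, target.position)
    err_mm = tissue.position - target.position
    h = spec.kidney_height_mm
    return TaskPerformance(
        task_index=spec.index,
        phase=spec.phase,
        prompt=submission.prompt,
        position_accuracy_mm=dist_mm,
        position_accuracy_norm=dist_mm / h,
        rotation_accuracy_deg=angular_difference(
            tissue.orientation, target.orientation
        ),
        per_axis_position_error_mm=err_mm,
        per_axis_position_error_norm=Vec3(err_mm.x / h, err_mm.y / h, err_mm.z / h),
        per_axis_angular_deviation=per_axis_angular_deviation(
            tissue.orientation, target.orientation
        ),
        completion_time_s=completion,
    )


def score_session(
    session: SubjectSession, protocol: list[TaskSpec]
) -> list[TaskPerformance]:
    """Score every submission of a session against the protocol, in order.

    The first task's completion time is measured from the session's first
    record timestamp (phase start), since no prior submission exists.
    """
    submissions = extract_submissions(session)
    if len(submissions) != len(protocol):
        raise ValueError(
            f"session has {len(submissions)} submissions, protocol defines "
            f"{len(protocol)} tasks"
        )
    prev = session.records[0].timestamp_s if session.records else 0.0
    scored: list[TaskPerformance] = []
    for sub, spec in zip(submissions, protocol):
        scored.append(score_task(sub, spec, prev))
        prev = sub.submit_timestamp_s
    return scored


def performance_frame(
    scored: list[TaskPerformance],
    subject_id: str | None = None,
    setup: str | None = None,
) -> pd.DataFrame:
    """Tabulate scored tasks, one row per task."""
    rows = []
    for i, p in enumerate(scored, start=1):
        rows.append(
            {
                "subject_id": subject_id,
                "setup": setup,
                "overall_task": i,
                "phase": p.phase.value,
                "task_index": p.task_index,
                "prompt": p.prompt.value,
                "position_accuracy_mm": p.position_accuracy_mm,
                "position_accuracy_norm": p.position_accuracy_norm,
                "rotation_accuracy_deg": p.rotation_accuracy_deg,
                "err_x_mm": p.per_axis_position_error_mm.x,
                "err_y_mm": p.per_axis_position_error_mm.y,
                "err_z_mm": p.per_axis_position_error_mm.z,
                "err_x_norm": p.per_axis_position_error_norm.x,
                "err_y_norm": p.per_axis_position_error_norm.y,
                "err_z_norm": p.per_axis_position_error_norm.z,
                "rot_dev_x_deg": p.per_axis_angular_deviation.dx,
                "rot_dev_y_deg": p.per_axis_angular_deviation.dy,
                "rot_dev_z_deg": p.per_axis_angular_deviation.dz,
                "rot_dev_degenerate": p.per_axis_angular_deviation.degenerate,
                "completion_time_s": p.completion_time_s,
            }
        )
    return pd.DataFrame(rows)


def axis_error_summary(placements: list[Vec3] | np.ndarray) -> AxisErrorSummary:
    """Per-axis median signed error and Euclidean bias for a set of placements.

    The target reference point is the origin; with an even number of
    placements the median is the mean of the two central order statistics.
    """
    if isinstance(placements, (list, tuple)):
        arr = np.array([p.as_array() if isinstance(p, Vec3) else p for p in placements])
    else:
        arr = np.asarray(placements, dtype=float)
    if arr.size == 0:
        raise ValueError("axis_error_summary requires at least one placement")
    arr = arr.reshape(-1, 3)
    med = np.median(arr, axis=0)
    return AxisErrorSummary(
        median_error=Vec3.from_array(med),
        bias=float(np.linalg.norm(med)),
        n=arr.shape[0],
    )


def detect_plateau(
    series, window_width: int = PLATEAU_WINDOW, variable: str = "value"
) -> PlateauResult:
    """Detect a performance plateau in a positive-valued task series.

    Walking backwards from the last task, a task i stays on the plateau while
    its relative deviation |x_i - m_i| / m_i from the trailing window mean
    m_i (window of up to ``window_width`` values ending at i) does not exceed
    1.  The plateau starts right after the first task (scanning backwards)
    whose relative deviation exceeds 1; if none does, it starts at task 1.
    The plateau level is the mean over the plateau tasks.  If even the last
    task deviates, no plateau was reached.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a non-empty 1-D array")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError(
            "series must be strictly positive (relative deviation is "
            "undefined at mean 0)"
        )
    n = x.size
    k = 0
    for i in range(n, 0, -1):  # 1-indexed task i
        window = x[max(0, i - window_width) : i]
        m = window.mean()
        if abs(x[i - 1] - m) / m > 1.0:
            k = i
            break
    reached = k < n
    if not reached:
        return PlateauResult(variable, window_width, None, None, False)
    level = float(x[k:].mean())
    return PlateauResult(variable, window_width, k + 1, level, True)


def cohort_plateau_summary(results: dict[str, PlateauResult]) -> dict:
    """Summarize per-subject plateau results across a cohort.

    Reports the median plateau level over subjects that reached a plateau,
    both the mean and the median of the onset tasks (a non-integer "mean
    trials to plateau" is the statistic usually quoted), and the count of
    subjects without a plateau.
    """
    reached = [r for r in results.values() if r.reached]
    if not reached:
        raise ValueError("no subject reached a plateau")
    levels = np.array([r.plateau_level for r in reached])
    onsets = np.array([r.onset_task for r in reached], dtype=float)
    return {
        "n_subjects": len(results),
        "n_reached": len(reached),
        "n_not_reached": len(results) - len(reached),
        "median_level": float(np.median(levels)),
        "mean_onset": float(onsets.mean()),
        "median_onset": float(np.median(onsets)),
    }
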