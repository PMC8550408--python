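"""Pose telemetry session I/O and per-task submission extraction.

Sessions are CSV streams in this package's canonical dialect: one row per
10 Hz pose sample or per event (task submission, position/rotation reset),
with session metadata (subject, setup, kidney height) duplicated on every
row so files can be concatenated and streamed.  Positions are written in mm
to 6 decimals, quaternion components to 9 decimals, timestamps to 3.
Analyses downstream consume only the ``submit`` rows; the 10 Hz samples are
retained for trajectory work.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .geometry import Orientation, Pose, Vec3
from .schedule import Phase, Prompt, assign_prompt

__all__ = [
    "Event",
    "Setup",
    "TelemetryRecord",
    "SubjectSession",
    "Submission",
    "SessionSchemaError",
    "write_session",
    "read_session",
    "extract_submissions",
    "COLUMNS",
]


class Event(str, enum.Enum):
    SAMPLE = "sample"
    SUBMIT = "submit"
    RESET_POSITION = "reset_position"
    RESET_ROTATION = "reset_rotation"


class Setup(str, enum.Enum):
    DESKTOP_2D = "desktop_2d"
    VR_TABLETOP = "vr_tabletop"
    VR_STANDUP = "vr_standup"


COLUMNS = [
    "subject_id",
    "setup",
    "kidney_height_mm",
    "phase",
    "task_index",
    "timestamp_s",
    "event",
    "tissue_x",
    "tissue_y",
    "tissue_z",
    "tissue_qw",
    "tissue_qx",
    "tissue_qy",
    "tissue_qz",
    "target_x",
    "target_y",
    "target_z",
    "target_qw",
    "target_qx",
    "target_qy",
    "target_qz",
]

_POS_DECIMALS = 6
_QUAT_DECIMALS = 9
_TIME_DECIMALS = 3


class SessionSchemaError(ValueError):
    """A telemetry file violates the documented session schema."""


@dataclass(frozen=True)
class TelemetryRecord:
    timestamp_s: float
    phase: Phase
    task_index: int
    tissue_pose: Pose
    target_pose: Pose
    event: Event = Event.SAMPLE


@dataclass
class SubjectSession:
    """One subject's full telemetry stream plus optional satisfaction rating."""

    subject_id: str
    setup: Setup
    kidney_height_mm: float
    records: list[TelemetryRecord] = field(default_factory=list)
    satisfaction: int | None = None

    def __post_init__(self) -> None:
        self.setup = Setup(self.setup)
        if self.satisfaction is not None and self.satisfaction not in range(1, 6):
            raise ValueError(f"satisfaction must be 1..5, got {self.satisfaction}")
        last = float("-inf")
        for i, r in enumerate(self.records):
            if r.timestamp_s < last:
                raise SessionSchemaError(
                    f"record {i}: timestamp {r.timestamp_s} decreases"
                )
            last = r.timestamp_s


@dataclass(frozen=True)
class Submission:
    """Block poses at the moment a task was submitted."""

    task_index: int
    phase: Phase
    tissue_pose: Pose
    target_pose: Pose
    submit_timestamp_s: float
    prompt: Prompt


def _pose_fields(prefix: str, pose: Pose) -> dict[str, float]:
    p, q = pose.position, pose.orientation
    return {
        f"{prefix}_x": round(p.x, _POS_DECIMALS),
        f"{prefix}_y": round(p.y, _POS_DECIMALS),
        f"{prefix}_z": round(p.z, _POS_DECIMALS),
        f"{prefix}_qw": round(q.w, _QUAT_DECIMALS),
        f"{prefix}_qx": round(q.x, _QUAT_DECIMALS),
        f"{prefix}_qy": round(q.y, _QUAT_DECIMALS),
        f"{prefix}_qz": round(q.z, _QUAT_DECIMALS),
    }


def session_to_frame(session: SubjectSession) -> pd.DataFrame:
    rows = []
    for r in session.records:
        row = {
            "subject_id": session.subject_id,
            "setup": session.setup.value,
            "kidney_height_mm": session.kidney_height_mm,
            "phase": r.phase.value,
            "task_index": r.task_index,
            "timestamp_s": round(r.timestamp_s, _TIME_DECIMALS),
            "event": r.event.value,
        }
        row.update(_pose_fields("tissue", r.tissue_pose))
        row.update(_pose_fields("target", r.target_pose))
        rows.append(row)
    return pd.DataFrame(rows, columns=COLUMNS)


def write_session(session: SubjectSession, destination: str | Path) -> None:
    """Write a session to CSV in the canonical dialect (lossless at the
    documented precision)."""
    session_to_frame(session).to_csv(destination, index=False)


def _read_pose(row: pd.Series, prefix: str, idx) -> Pose:
    try:
        return Pose(
            Vec3(row[f"{prefix}_x"], row[f"{prefix}_y"], row[f"{prefix}_z"]),
            Orientation(
                row[f"{prefix}_qw"],
                row[f"{prefix}_qx"],
                row[f"{prefix}_qy"],
                row[f"{prefix}_qz"],
            ),
        )
    except ValueError as exc:
        raise SessionSchemaError(f"row {idx}: invalid {prefix} pose: {exc}") from exc


def read_session(source: str | Path, satisfaction: int | None = None) -> SubjectSession:
    """Read and validate a session CSV.

    Raises :class:`SessionSchemaError` naming the offending row and field on
    missing columns, unknown labels, non-monotone timestamps, or duplicate
    submit events for a task.
    """
    df = pd.read_csv(source)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SessionSchemaError(f"missing columns: {missing}")
    if df.empty:
        raise SessionSchemaError("empty session: no metadata rows to read")
    meta = df.iloc[0]
    records: list[TelemetryRecord] = []
    seen_submits: set[tuple[str, int]] = set()
    last_t = float("-inf")
    for idx, row in df.iterrows():
        try:
            phase = Phase(row["phase"])
        except ValueError:
            raise SessionSchemaError(f"row {idx}: unknown phase {row['phase']!r}")
        try:
            event = Event(row["event"])
        except ValueError:
            raise SessionSchemaError(f"row {idx}: unknown event {row['event']!r}")
        t = float(row["timestamp_s"])
        if t < last_t:
            raise SessionSchemaError(
                f"row {idx}: field timestamp_s non-monotone ({t} < {last_t})"
            )
        last_t = t
        task_index = int(row["task_index"])
        if event is Event.SUBMIT:
            key = (phase.value, task_index)
            if key in seen_submits:
                raise SessionSchemaError(
                    f"row {idx}: duplicate submit for {phase.value} task {task_index}"
                )
            seen_submits.add(key)
        records.append(
            TelemetryRecord(
                timestamp_s=t,
                phase=phase,
                task_index=task_index,
                tissue_pose=_read_pose(row, "tissue", idx),
                target_pose=_read_pose(row, "target", idx),
                event=event,
            )
        )
    return SubjectSession(
        subject_id=str(meta["subject_id"]),
        setup=Setup(meta["setup"]),
        kidney_height_mm=float(meta["kidney_height_mm"]),
        records=records,
        satisfaction=satisfaction,
    )


def extract_submissions(session: SubjectSession) -> list[Submission]:
    """One :class:`Submission` per submit event, in stream order.

    The poses are taken from the submit row itself (the last logged state of
    the task).  A session whose record stream contains a task with samples
    but no submit event is incomplete and rejected.
    """
    submissions: list[Submission] = []
    submitted: set[tuple[str, int]] = set()
    seen_tasks: set[tuple[str, int]] = set()
    for r in session.records:
        seen_tasks.add((r.phase.value, r.task_index))
        if r.event is Event.SUBMIT:
            submitted.add((r.phase.value, r.task_index))
            submissions.append(
                Submission(
                    task_index=r.task_index,
                    phase=r.phase,
                    tissue_pose=r.tissue_pose,
                    target_pose=r.target_pose,
                    submit_timestamp_s=r.timestamp_s,
                    prompt=assign_prompt(r.phase, r.task_index),
                )
            )
    unsubmitted = seen_tasks - submitted
    if unsubmitted:
        raise SessionSchemaError(
            f"incomplete session: tasks without submit event: {sorted(unsubmitted)}"
        )
    return submissions
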