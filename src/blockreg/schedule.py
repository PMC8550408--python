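"""Task protocol generation: 1 tutorial + 14 ramp-up + 30 plateau tasks.

Difficulty in the ramp-up phase is a linear schedule in the interpolation
fraction t = task_index / 14: the start-to-target distance grows from 30% to
200% of the kidney height, the block edge length shrinks from 20% to 5% of
the height, and the target rotation moves along a spherical interpolation
from identity to the Euler end rotation (0, 270, 180), i.e. the scalar
angular difficulty grows linearly 0 -> 180 degrees.  Plateau tasks are all
identical: distance 115% of height and size 12.5% (the schedule midpoints),
at the maximum angular difference.  Ramp-up tasks alternate audio prompts:
odd tasks focus on speed, even tasks on accuracy.

Normalizing every length by the displayed kidney height makes the schedule
identical across the 2D Desktop (113 mm) and VR (590 mm) conditions.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    Orientation,
    Pose,
    Vec3,
    angular_difference,
    euler_to_orientation,
    lerp,
    slerp,
)

__all__ = [
    "Phase",
    "Prompt",
    "DifficultyEndpoints",
    "ProtocolConfig",
    "TaskSpec",
    "difficulty_at",
    "assign_prompt",
    "build_protocol",
    "protocol_to_frame",
    "write_protocol_csv",
    "write_protocol_json",
]


class Phase(str, enum.Enum):
    TUTORIAL = "tutorial"
    RAMP_UP = "ramp_up"
    PLATEAU = "plateau"


class Prompt(str, enum.Enum):
    SPEED = "speed"
    ACCURACY = "accuracy"
    NONE = "none"


@dataclass(frozen=True)
class DifficultyEndpoints:
    """Start (easiest) and end (hardest) value of one difficulty parameter."""

    start: float
    end: float

    def at(self, t: float) -> float:
        return lerp(self.start, self.end, t)


@dataclass(frozen=True)
class ProtocolConfig:
    """Study protocol configuration.

    Lengths are fractions of the kidney height; the end rotation is the Euler
    triple (x, y, z) in degrees of the hardest ramp-up target orientation.
    """

    n_tutorial: int = 1
    n_ramp_up: int = 14
    n_plateau: int = 30
    distance: DifficultyEndpoints = field(
        default_factory=lambda: DifficultyEndpoints(0.30, 2.00)
    )
    size: DifficultyEndpoints = field(
        default_factory=lambda: DifficultyEndpoints(0.20, 0.05)
    )
    end_rotation_euler_deg: tuple[float, float, float] = (0.0, 270.0, 180.0)
    kidney_height_mm: float = 113.0
    seed: int | None = None
    offset_direction: str = "+x"  # "+x" or "random" (seeded unit direction)

    def __post_init__(self) -> None:
        if min(self.n_tutorial, self.n_ramp_up, self.n_plateau) <= 0:
            raise ValueError("task counts must be positive")
        if self.kidney_height_mm <= 0:
            raise ValueError("kidney height must be positive")
        if self.offset_direction not in ("+x", "random"):
            raise ValueError(f"unknown offset_direction {self.offset_direction!r}")

    @property
    def n_tasks(self) -> int:
        return self.n_tutorial + self.n_ramp_up + self.n_plateau

    def end_orientation(self) -> Orientation:
        return euler_to_orientation(*self.end_rotation_euler_deg)

    @classmethod
    def from_json(cls, source: str | Path) -> "ProtocolConfig":
        raw = json.loads(Path(source).read_text())
        if "distance" in raw:
            raw["distance"] = DifficultyEndpoints(*raw["distance"])
        if "size" in raw:
            raw["size"] = DifficultyEndpoints(*raw["size"])
        if "end_rotation_euler_deg" in raw:
            raw["end_rotation_euler_deg"] = tuple(raw["end_rotation_euler_deg"])
        return cls(**raw)


@dataclass(frozen=True)
class TaskSpec:
    """One registration task: difficulty parameters plus realized poses (mm)."""

    phase: Phase
    index: int
    t: float
    distance_frac: float
    size_frac: float
    angular_difference_deg: float
    prompt: Prompt
    target_pose: Pose
    start_pose: Pose
    kidney_height_mm: float


def difficulty_at(
    config: ProtocolConfig, phase: Phase, index: int
) -> tuple[float, float, float]:
    """Difficulty triple (distance_frac, size_frac, angle_deg) for one task.

    Tutorial is task 0 of the ramp schedule (t = 0); ramp-up task i has
    t = i / n_ramp_up; every plateau task sits at the schedule midpoints for
    distance and size but at the maximum angular difference.
    """
    phase = Phase(phase)
    if phase is Phase.TUTORIAL:
        if index != 0:
            raise ValueError(f"tutorial index must be 0, got {index}")
        t = 0.0
    elif phase is Phase.RAMP_UP:
        if not 1 <= index <= config.n_ramp_up:
            raise ValueError(f"ramp-up index {index} outside 1..{config.n_ramp_up}")
        t = index / config.n_ramp_up
    else:
        if not 1 <= index <= config.n_plateau:
            raise ValueError(f"plateau index {index} outside 1..{config.n_plateau}")
        end_angle = angular_difference(Orientation.identity(), config.end_orientation())
        return (
            (config.distance.start + config.distance.end) / 2.0,
            (config.size.start + config.size.end) / 2.0,
            end_angle,
        )
    end_angle = angular_difference(Orientation.identity(), config.end_orientation())
    return (config.distance.at(t), config.size.at(t), lerp(0.0, end_angle, t))


def assign_prompt(phase: Phase, index: int) -> Prompt:
    """Audio prompt for a task: ramp-up alternates speed (odd) / accuracy (even);
    plateau tasks are all performed as fast as possible."""
    phase = Phase(phase)
    if phase is Phase.TUTORIAL:
        return Prompt.NONE
    if phase is Phase.RAMP_UP:
        return Prompt.SPEED if index % 2 == 1 else Prompt.ACCURACY
    return Prompt.SPEED


def _offset_direction(config: ProtocolConfig, rng: np.random.Generator) -> np.ndarray:
    if config.offset_direction == "+x":
        return np.array([1.0, 0.0, 0.0])
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def build_protocol(config: ProtocolConfig | None = None) -> list[TaskSpec]:
    """Build the ordered task list for one setup.

    The target block sits at the organ bounding-box center (the origin); the
    start pose is displaced from it by distance_frac * kidney_height along the
    configured direction, with identity start orientation.  The target
    orientation at fraction t is slerp(identity, end_rotation, t).
    Deterministic given the config seed.
    """
    config = config or ProtocolConfig()
    rng = np.random.default_rng(config.seed)
    q_end = config.end_orientation()
    identity = Orientation.identity()
    tasks: list[TaskSpec] = []
    schedule: list[tuple[Phase, int, float]] = [(Phase.TUTORIAL, 0, 0.0)]
    schedule += [
        (Phase.RAMP_UP, i, i / config.n_ramp_up) for i in range(1, config.n_ramp_up + 1)
    ]
    schedule += [(Phase.PLATEAU, i, 1.0) for i in range(1, config.n_plateau + 1)]
    for phase, index, t in schedule:
        dist_frac, size_frac, angle = difficulty_at(config, phase, index)
        q_target = slerp(identity, q_end, t)
        direction = _offset_direction(config, rng)
        offset = direction * dist_frac * config.kidney_height_mm
        target = Pose(Vec3(0.0, 0.0, 0.0), q_target)
        start = Pose(Vec3.from_array(offset), identity)
        tasks.append(
            TaskSpec(
                phase=phase,
                index=index,
                t=t,
                distance_frac=dist_frac,
                size_frac=size_frac,
                angular_difference_deg=angle,
                prompt=assign_prompt(phase, index),
                target_pose=target,
                start_pose=start,
                kidney_height_mm=config.kidney_height_mm,
            )
        )
    return tasks


def protocol_to_frame(tasks: list[TaskSpec]) -> pd.DataFrame:
    rows = []
    for s in tasks:
        rows.append(
            {
                "phase": s.phase.value,
                "index": s.index,
                "t": s.t,
                "distance_frac": s.distance_frac,
                "size_frac": s.size_frac,
                "angle_deg": s.angular_difference_deg,
                "prompt": s.prompt.value,
                "target_x": s.target_pose.position.x,
                "target_y": s.target_pose.position.y,
                "target_z": s.target_pose.position.z,
                "target_qw": s.target_pose.orientation.w,
                "target_qx": s.target_pose.orientation.x,
                "target_qy": s.target_pose.orientation.y,
                "target_qz": s.target_pose.orientation.z,
                "start_x": s.start_pose.position.x,
                "start_y": s.start_pose.position.y,
                "start_z": s.start_pose.position.z,
                "start_qw": s.start_pose.orientation.w,
                "start_qx": s.start_pose.orientation.x,
                "start_qy": s.start_pose.orientation.y,
                "start_qz": s.start_pose.orientation.z,
                "kidney_height_mm": s.kidney_height_mm,
            }
        )
    return pd.DataFrame(rows)


def write_protocol_csv(tasks: list[TaskSpec], destination: str | Path) -> None:
    protocol_to_frame(tasks).to_csv(destination, index=False)


def write_protocol_json(tasks: list[TaskSpec], destination: str | Path) -> None:
    Path(destination).write_text(
        json.dumps(protocol_to_frame(tasks).to_dict(orient="records"), indent=1)
    )
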