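"""3D vector and orientation primitives for tissue-block registration metrics.

All orientations are unit quaternions stored in a right-handed, y-up frame.
Euler angles follow the z-x-y composition convention of the game engine the
registration interfaces were built in: a rotation of (x, y, z) degrees is
applied as Rz first, then Rx, then Ry, all about fixed world axes, i.e.
``R = Ry(y) @ Rx(x) @ Rz(z)``.  Scalar metrics (distances, angular
differences) are invariant to handedness; only the per-axis Euler
decomposition depends on this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "Vec3",
    "Orientation",
    "Pose",
    "AxisDeviation",
    "lerp",
    "slerp",
    "angular_difference",
    "euler_to_orientation",
    "orientation_to_euler",
    "centroid_distance",
    "per_axis_angular_deviation",
    "wrap_angle",
]

#: |x Euler angle| this close (degrees) to 90 marks a degenerate (gimbal-locked)
#: per-axis decomposition.
GIMBAL_TOL_DEG = 1e-4


def _require_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"non-finite argument: {v!r}")


@dataclass(frozen=True)
class Vec3:
    """Point or displacement in 3D space (mm, or dimensionless when normalized)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        _require_finite(self.x, self.y, self.z)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Vec3":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def __add__(self, other: "Vec3") -> "Vec3":
        return Vec3(self.x + other.x, self.y + other.y, self.z + other.z)

    def __sub__(self, other: "Vec3") -> "Vec3":
        return Vec3(self.x - other.x, self.y - other.y, self.z - other.z)

    def __mul__(self, s: float) -> "Vec3":
        return Vec3(self.x * s, self.y * s, self.z * s)

    __rmul__ = __mul__


@dataclass(frozen=True)
class Orientation:
    """Unit quaternion (w, x, y, z).

    Normalized at construction and canonicalized to w >= 0: q and -q denote
    the same rotation, and every metric here is invariant under negation.
    """

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        _require_finite(self.w, self.x, self.y, self.z)
        n = math.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2)
        if n < 1e-12:
            raise ValueError("zero-norm quaternion is not an orientation")
        sign = -1.0 if self.w < 0 else 1.0
        object.__setattr__(self, "w", sign * self.w / n)
        object.__setattr__(self, "x", sign * self.x / n)
        object.__setattr__(self, "y", sign * self.y / n)
        object.__setattr__(self, "z", sign * self.z / n)

    @classmethod
    def identity(cls) -> "Orientation":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float) -> "Orientation":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n < 1e-12:
            raise ValueError("zero-length rotation axis")
        half = math.radians(angle_deg) / 2.0
        s = math.sin(half) / n
        return cls(math.cos(half), axis[0] * s, axis[1] * s, axis[2] * s)

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z], dtype=float)

    def compose(self, other: "Orientation") -> "Orientation":
        """Hamilton product self * other (apply `other` first, then self)."""
        w1, x1, y1, z1 = self.w, self.x, self.y, self.z
        w2, x2, y2, z2 = other.w, other.x, other.y, other.z
        return Orientation(
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        )

    def inverse(self) -> "Orientation":
        return Orientation(self.w, -self.x, -self.y, -self.z)

    def as_matrix(self) -> np.ndarray:
        w, x, y, z = self.w, self.x, self.y, self.z
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )


@dataclass(frozen=True)
class Pose:
    """Position + orientation of one block."""

    position: Vec3
    orientation: Orientation


class AxisDeviation(NamedTuple):
    """Signed per-axis angular deviations (degrees), with gimbal-lock flag."""

    dx: float
    dy: float
    dz: float
    degenerate: bool = False


def lerp(start: float, end: float, t: float) -> float:
    """Clamped linear interpolation between ``start`` and ``end``.

    Returns ``start`` for t <= 0, ``end`` for t >= 1, and
    ``start + (end - start) * t`` in between.  Used to ramp task-difficulty
    parameters across the 14 ramp-up tasks.
    """
    _require_finite(start, end, t)
    if t <= 0.0:
        return start
    if t >= 1.0:
        return end
    return start + (end - start) * t


def slerp(q0: Orientation, q1: Orientation, t: float) -> Orientation:
    """Shortest-arc spherical interpolation, with t clamped to [0, 1]."""
    _require_finite(t)
    t = min(max(t, 0.0), 1.0)
    a = q0.as_array()
    b = q1.as_array()
    dot = float(np.dot(a, b))
    if dot < 0.0:  # take the short way around the double cover
        b = -b
        dot = -dot
    dot = min(dot, 1.0)
    if dot > 1.0 - 1e-12:
        out = a + t * (b - a)  # nearly parallel: nlerp is exact enough
    else:
        theta = math.acos(dot)
        s = math.sin(theta)
        out = (math.sin((1 - t) * theta) / s) * a + (math.sin(t * theta) / s) * b
    return Orientation(*out)


def angular_difference(q0: Orientation, q1: Orientation) -> float:
    """Scalar angular distance between two orientations, in degrees [0, 180].

    0 means identical rotation, 180 diametrically opposite; symmetric and
    invariant under negation of either quaternion.
    """
    dot = abs(float(np.dot(q0.as_array(), q1.as_array())))
    dot = min(dot, 1.0)
    return math.degrees(2.0 * math.acos(dot))


def euler_to_orientation(x_deg: float, y_deg: float, z_deg: float) -> Orientation:
    """Orientation from Euler angles composed z, then x, then y about world axes."""
    _require_finite(x_deg, y_deg, z_deg)
    qx = Orientation.from_axis_angle((1, 0, 0), x_deg)
    qy = Orientation.from_axis_angle((0, 1, 0), y_deg)
    qz = Orientation.from_axis_angle((0, 0, 1), z_deg)
    return qy.compose(qx).compose(qz)  # R = Ry Rx Rz


def orientation_to_euler(q: Orientation) -> tuple[float, float, float, bool]:
    """Decompose into (x, y, z) degrees in the z-x-y convention.

    Returns a fourth flag that is True when the decomposition is
    gimbal-degenerate (|x| within GIMBAL_TOL_DEG of 90): there the y/z split
    is not unique and y is reported with z fixed at 0.
    """
    m = q.as_matrix()
    # R = Ry(y) Rx(x) Rz(z):  m[1,2] = -sin x;  m[0,2] = sin y cos x;
    # m[2,2] = cos y cos x;  m[1,0] = cos x sin z;  m[1,1] = cos x cos z.
    sx = -m[1, 2]
    sx = min(max(sx, -1.0), 1.0)
    x = math.degrees(math.asin(sx))
    if abs(abs(x) - 90.0) <= GIMBAL_TOL_DEG:
        # cos x ~ 0: only y +/- z is determined; report it all as y.
        y = math.degrees(math.atan2(-m[2, 0], m[0, 0]))
        return x, y, 0.0, True
    y = math.degrees(math.atan2(m[0, 2], m[2, 2]))
    z = math.degrees(math.atan2(m[1, 0], m[1, 1]))
    return x, y, z, False


def centroid_distance(p: Vec3, q: Vec3) -> float:
    """Euclidean distance between two block centroids (mm)."""
    return float(np.linalg.norm(p.as_array() - q.as_array()))


def wrap_angle(deg: float) -> float:
    """Wrap an angle to (-180, 180], ties at +/-180 resolved to +180."""
    wrapped = (deg + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


def per_axis_angular_deviation(
    q_tissue: Orientation, q_target: Orientation
) -> AxisDeviation:
    """Signed per-axis rotation deviations tissue - target, in (-180, 180] degrees.

    Computed as wrapped differences of the z-x-y Euler decompositions of the
    two orientations.  When either decomposition is gimbal-degenerate the
    result is flagged; the scalar :func:`angular_difference` is unaffected by
    that degeneracy.
    """
    xt, yt, zt, dt = orientation_to_euler(q_tissue)
    xg, yg, zg, dg = orientation_to_euler(q_target)
    return AxisDeviation(
        wrap_angle(xt - xg),
        wrap_angle(yt - yg),
        wrap_angle(zt - zg),
        degenerate=dt or dg,
    )
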