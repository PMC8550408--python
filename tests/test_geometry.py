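"""Geometry primitives: interpolation, angular metrics, Euler conventions.

The independent oracle for angular distances is the rotation-matrix trace
formula arccos((tr(R) - 1) / 2), built from explicitly assembled single-axis
matrices (and cross-checked via scipy's Rotation class, which plays no part
in the implementation).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from blockreg import (
    Orientation,
    Vec3,
    angular_difference,
    centroid_distance,
    euler_to_orientation,
    lerp,
    per_axis_angular_deviation,
    slerp,
)
from blockreg.geometry import orientation_to_euler, wrap_angle


def rot_x(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rot_y(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rot_z(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def trace_angle(r0: np.ndarray, r1: np.ndarray) -> float:
    """Oracle: angle between two rotation matrices via the trace formula."""
    rel = r0.T @ r1
    c = (np.trace(rel) - 1.0) / 2.0
    return math.degrees(math.acos(min(max(c, -1.0), 1.0)))


def random_orientation(rng) -> Orientation:
    return Orientation(*rng.normal(size=4))


class TestLerp:
    @pytest.mark.parametrize(
        "start,end,t,expected",
        [
            (30, 200, 0, 30),  # boundary clamp
            (30, 200, 0.5, 115),  # schedule midpoint: 115% kidney height
            (20, 5, 1, 5),  # hardest size: 5% kidney height
            (30, 200, 3 / 14, pytest.approx(66.428571, abs=1e-4)),
            (30, 200, -2, 30),
            (30, 200, 7, 200),
        ],
    )
    def test_values(self, start, end, t, expected):
        assert lerp(start, end, t) == expected

    @given(
        a=st.floats(-1e6, 1e6),
        b=st.floats(-1e6, 1e6),
        t=st.floats(-2, 2),
    )
    @settings(derandomize=True, max_examples=200)
    def test_clamped_between_endpoints(self, a, b, t):
        v = lerp(a, b, t)
        assert min(a, b) - 1e-9 <= v <= max(a, b) + 1e-9

    @given(t=st.floats(-3, 3))
    @settings(derandomize=True)
    def test_degenerate_endpoints(self, t):
        assert lerp(5.0, 5.0, t) == 5.0

    def test_monotone_in_t(self):
        ts = np.linspace(0, 1, 50)
        vals = [lerp(1.0, 9.0, t) for t in ts]
        assert np.all(np.diff(vals) >= 0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            lerp(float("nan"), 1.0, 0.5)


class TestAngularDifference:
    def test_identity_is_zero(self, rng):
        q = random_orientation(rng)
        assert angular_difference(q, q) == pytest.approx(0.0, abs=1e-9)

    def test_end_rotation_is_180(self):
        """The hardest ramp-up rotation (0, 270, 180) is diametrically
        opposite the identity: tr(Ry(270) Rx(0) Rz(180)) = -1."""
        q = euler_to_orientation(0, 270, 180)
        assert angular_difference(Orientation.identity(), q) == pytest.approx(180.0)
        oracle = trace_angle(np.eye(3), rot_y(270) @ rot_x(0) @ rot_z(180))
        assert oracle == pytest.approx(180.0)

    def test_single_axis_90(self):
        q = euler_to_orientation(0, 90, 0)
        assert angular_difference(Orientation.identity(), q) == pytest.approx(
            trace_angle(np.eye(3), rot_y(90)), abs=1e-9
        )

    def test_matches_trace_oracle_on_random_pairs(self, rng):
        for _ in range(500):
            q0, q1 = random_orientation(rng), random_orientation(rng)
            got = angular_difference(q0, q1)
            want = trace_angle(q0.as_matrix(), q1.as_matrix())
            assert got == pytest.approx(want, abs=1e-6)
            assert 0.0 <= got <= 180.0

    def test_symmetric_and_negation_invariant(self, rng):
        q0, q1 = random_orientation(rng), random_orientation(rng)
        neg = Orientation(-q1.w, -q1.x, -q1.y, -q1.z)
        assert angular_difference(q0, q1) == pytest.approx(
            angular_difference(q1, q0), abs=1e-12
        )
        assert angular_difference(q0, neg) == pytest.approx(
            angular_difference(q0, q1), abs=1e-9
        )

    def test_matches_scipy_cross_check(self, rng):
        q0, q1 = random_orientation(rng), random_orientation(rng)
        r0 = Rotation.from_matrix(q0.as_matrix())
        r1 = Rotation.from_matrix(q1.as_matrix())
        want = math.degrees((r0.inv() * r1).magnitude())
        assert angular_difference(q0, q1) == pytest.approx(want, abs=1e-8)


class TestSlerp:
    def test_endpoints(self, rng):
        q0, q1 = random_orientation(rng), random_orientation(rng)
        assert angular_difference(slerp(q0, q1, 0), q0) == pytest.approx(0, abs=1e-9)
        assert angular_difference(slerp(q0, q1, 1), q1) == pytest.approx(0, abs=1e-9)

    def test_quarter_turn(self):
        q1 = Orientation.from_axis_angle((0, 0, 1), 180)
        mid = slerp(Orientation.identity(), q1, 0.25)
        assert angular_difference(Orientation.identity(), mid) == pytest.approx(
            45.0, abs=1e-9
        )

    def test_angle_linear_in_t(self, rng):
        q0, q1 = random_orientation(rng), random_orientation(rng)
        total = angular_difference(q0, q1)
        for t in np.linspace(0, 1, 11):
            assert angular_difference(q0, slerp(q0, q1, t)) == pytest.approx(
                t * total, abs=1e-6
            )

    def test_clamps_t(self, rng):
        q0, q1 = random_orientation(rng), random_orientation(rng)
        assert angular_difference(slerp(q0, q1, 1.7), q1) == pytest.approx(0, abs=1e-9)


class TestEulerConvention:
    def test_zero_is_identity(self):
        q = euler_to_orientation(0, 0, 0)
        assert angular_difference(q, Orientation.identity()) == pytest.approx(0)

    @pytest.mark.parametrize("x,y,z", [(30, 0, 0), (0, 75, 0), (0, 0, -120)])
    def test_single_axis(self, x, y, z):
        q = euler_to_orientation(x, y, z)
        want = rot_y(y) @ rot_x(x) @ rot_z(z)
        assert np.allclose(q.as_matrix(), want, atol=1e-12)

    def test_composition_order_z_x_y(self, rng):
        x, y, z = rng.uniform(-180, 180, size=3)
        q = euler_to_orientation(x, y, z)
        assert np.allclose(q.as_matrix(), rot_y(y) @ rot_x(x) @ rot_z(z), atol=1e-12)

    def test_round_trip_away_from_gimbal(self, rng):
        for _ in range(200):
            x = rng.uniform(-85, 85)
            y, z = rng.uniform(-179, 179, size=2)
            rx, ry, rz, degen = orientation_to_euler(euler_to_orientation(x, y, z))
            assert not degen
            assert (rx, ry, rz) == (
                pytest.approx(x, abs=1e-7),
                pytest.approx(y, abs=1e-7),
                pytest.approx(z, abs=1e-7),
            )


class TestPerAxisDeviation:
    def test_zero_for_equal(self, rng):
        q = random_orientation(rng)
        d = per_axis_angular_deviation(q, q)
        assert (d.dx, d.dy, d.dz) == (0, 0, 0)

    def test_single_axis(self):
        d = per_axis_angular_deviation(
            Orientation.identity(), euler_to_orientation(0, 30, 0)
        )
        assert d.dy == pytest.approx(-30, abs=1e-9)
        assert d.dx == pytest.approx(0, abs=1e-9)
        assert d.dz == pytest.approx(0, abs=1e-9)

    def test_wrap_rule(self):
        """y = 350 deg is 10 deg short of a full turn: the signed deviation
        wraps into (-180, 180]."""
        d = per_axis_angular_deviation(
            Orientation.identity(), euler_to_orientation(10, 350, 0)
        )
        assert d.dy == pytest.approx(10, abs=1e-9)  # 0 - 350 wraps to +10
        assert d.dx == pytest.approx(-10, abs=1e-9)

    def test_wrap_tie_goes_positive(self):
        assert wrap_angle(-180.0) == 180.0
        assert wrap_angle(180.0) == 180.0

    def test_gimbal_lock_flagged(self):
        d = per_axis_angular_deviation(
            Orientation.identity(), euler_to_orientation(90, 33, 0)
        )
        assert d.degenerate
        # the scalar metric is unaffected by the degeneracy
        assert 0 <= angular_difference(
            Orientation.identity(), euler_to_orientation(90, 33, 0)
        ) <= 180


class TestVectors:
    def test_distance_examples(self):
        assert centroid_distance(Vec3(1, 2, 3), Vec3(1, 2, 3)) == 0
        assert centroid_distance(Vec3(0, 0, 0), Vec3(3, 4, 0)) == 5

    def test_distance_matches_componentwise_oracle(self, rng):
        p, q = rng.normal(size=3), rng.normal(size=3)
        want = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
        assert centroid_distance(Vec3(*p), Vec3(*q)) == pytest.approx(want)

    def test_vec3_rejects_non_finite(self):
        with pytest.raises(ValueError):
            Vec3(1.0, float("inf"), 0.0)

    def test_orientation_canonical_w_nonnegative(self):
        q = Orientation(-0.5, 0.5, 0.5, 0.5)
        assert q.w >= 0
        assert abs(np.linalg.norm(q.as_array()) - 1) < 1e-12
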