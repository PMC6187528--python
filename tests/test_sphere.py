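import numpy as np
import pytest

from cellspin.evaluate import axis_angle_deg
from cellspin.sphere import (DegeneratePairError, InsufficientMotionError,
                             RotationEstimate, SphereModel, axis_from_pair,
                             back_project, estimate_axis, estimate_rotation,
                             lift_flow, point_velocity, to_angular_velocity)
from cellspin.synthetic import analytic_flow, rotation_matrix


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


class TestBackProject:
    sphere = SphereModel(cx=50.0, cy=50.0, r=40.0)

    def test_center_maps_to_pole(self):
        np.testing.assert_allclose(back_project((50.0, 50.0), self.sphere),
                                   [0.0, 0.0, 40.0])

    def test_admissible_rim_closed_form(self):
        rho_max = 0.95
        p = back_project((50.0, 50.0 + 40.0 * rho_max), self.sphere)
        np.testing.assert_allclose(
            p, [40 * rho_max, 0.0, 40 * np.sqrt(1 - rho_max ** 2)], atol=1e-12)

    def test_outside_disc_rejected(self):
        with pytest.raises(ValueError, match="disc"):
            back_project((50.0, 89.9), self.sphere)

    def test_sphere_constraint_on_random_pixels(self):
        rng = np.random.default_rng(0)
        count = 0
        while count < 1000:
            row, col = rng.uniform(10, 90, 2)
            if np.hypot(col - 50, row - 50) > 0.95 * 40:
                continue
            p = back_project((row, col), self.sphere)
            assert abs(p @ p - 40.0 ** 2) < 1e-9 * 40.0
            assert p[2] >= 0
            count += 1


class TestLiftFlow:
    def test_zero_flow_lifts_to_zero(self):
        p = np.array([10.0, -5.0, 30.0])
        np.testing.assert_array_equal(lift_flow(p, (0.0, 0.0)), 0.0)

    def test_pole_keeps_planar_components(self):
        vo = lift_flow(np.array([0.0, 0.0, 40.0]), (0.7, 0.3))
        np.testing.assert_allclose(vo, [0.7, -0.3, 0.0])

    def test_tangency_constraint(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            x, y = rng.uniform(-20, 20, 2)
            z = np.sqrt(max(40.0 ** 2 - x * x - y * y, 0.0))
            p = np.array([x, y, z])
            uv = rng.uniform(-2, 2, 2)
            vo = lift_flow(p, tuple(uv), r=40.0)
            assert abs(vo @ p) < 1e-9 * 40.0 * max(np.linalg.norm(vo), 1.0)

    def test_rim_guard(self):
        p = np.array([39.9, 0.0, np.sqrt(40 ** 2 - 39.9 ** 2)])
        with pytest.raises(ValueError, match="rim"):
            lift_flow(p, (1.0, 0.0), r=40.0)


class TestAxisFromPair:
    def test_orthogonal_tangents_at_pole(self):
        direction, _ = axis_from_pair([1.0, 0, 0], [0, 1.0, 0], r=1.0)
        np.testing.assert_allclose(direction, [0, 0, 1.0])

    def test_parallel_vectors_degenerate(self):
        with pytest.raises(DegeneratePairError):
            axis_from_pair([1.0, 2.0, 0.0], [2.0, 4.0, 0.0], r=1.0)

    def test_forward_model_recovers_known_axis(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = _random_unit(rng)
            p1, p2 = _random_unit(rng) * 40, _random_unit(rng) * 40
            vo1, vo2 = np.cross(a, p1), np.cross(a, p2)
            direction, _ = axis_from_pair(vo1, vo2, r=40.0)
            assert min(np.linalg.norm(direction - a),
                       np.linalg.norm(direction + a)) < 1e-9


class TestEstimateAxis:
    sphere = SphereModel(cx=60.0, cy=60.0, r=50.0)

    def test_in_plane_spin_axis(self):
        field = analytic_flow(self.sphere, [0, 0, 1], 2.0, shape=(121, 121))
        axis, residual, n = estimate_axis(field, self.sphere)
        np.testing.assert_allclose(axis, [0, 0, 1.0], atol=1e-9)
        assert residual < 1e-6
        assert n >= 50

    def test_tumble_axis_with_sign(self):
        field = analytic_flow(self.sphere, [1, 0, 0], 2.0, shape=(121, 121))
        axis, _, _ = estimate_axis(field, self.sphere)
        np.testing.assert_allclose(axis, [1.0, 0, 0], atol=1e-9)

    def test_zero_flow_insufficient_motion(self):
        from cellspin.flow import FlowField
        field = FlowField(np.zeros((121, 121)), np.zeros((121, 121)))
        with pytest.raises(InsufficientMotionError):
            estimate_axis(field, self.sphere)


class TestPointVelocity:
    def test_unit_ratio(self):
        p = np.array([0.0, 360.0, 0.0])
        axis = np.array([0.0, 0.0, 1.0])
        vo = np.array([2 * np.pi, 0.0, 0.0])
        assert point_velocity(vo, p, axis, d_min=1.0) == pytest.approx(1.0)

    def test_equator_forward_kinematics(self):
        omega = np.deg2rad(1.0)
        p = np.array([1.0, 0.0, 0.0])
        vo = omega * np.cross([0, 0, 1.0], p)
        v = point_velocity(vo, p, np.array([0, 0, 1.0]), d_min=0.2)
        assert v == pytest.approx(1.0, rel=1e-12)

    def test_near_axis_guard(self):
        with pytest.raises(ValueError, match="d_min"):
            point_velocity(np.ones(3), np.array([0.0, 0.0, 40.0]),
                           np.array([0, 0, 1.0]), d_min=8.0)


class TestEstimateRotation:
    sphere = SphereModel(cx=60.0, cy=60.0, r=50.0)

    def test_analytic_spin_amplitude(self):
        field = analytic_flow(self.sphere, [0, 0, 1], 2.0, shape=(121, 121))
        est = estimate_rotation(field, self.sphere)
        assert est.deg_per_frame == pytest.approx(2.0, abs=1e-3)
        assert not est.out_of_band

    def test_oracle_equivalence_random_axes(self):
        # forward model omega * (a x p): axis < 1 deg, amplitude < 1%
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = _random_unit(rng)
            deg = rng.uniform(0.5, 4.0)
            field = analytic_flow(self.sphere, a, deg, shape=(121, 121))
            est = estimate_rotation(field, self.sphere)
            assert axis_angle_deg(est.axis, a) < 1.0
            assert abs(est.deg_per_frame - deg) / deg < 0.01

    def test_in_plane_equivariance(self):
        # rotating flow + sphere by an in-plane rotation rotates the axis
        rng = np.random.default_rng(4)
        a = _random_unit(rng)
        field = analytic_flow(self.sphere, a, 2.0, shape=(121, 121))
        est = estimate_rotation(field, self.sphere)
        phi = 90.0
        rz = rotation_matrix([0, 0, 1], phi)
        a_rot = rz @ a
        field_rot = analytic_flow(self.sphere, a_rot, 2.0, shape=(121, 121))
        est_rot = estimate_rotation(field_rot, self.sphere)
        assert axis_angle_deg(est_rot.axis, rz @ est.axis) < 1.0

    def test_fast_spin_flagged_out_of_band(self):
        field = analytic_flow(self.sphere, [0, 0, 1], 5.0, shape=(121, 121))
        assert estimate_rotation(field, self.sphere).out_of_band


class TestAngularVelocity:
    def test_camera_band_limit(self):
        rad_per_min, _ = to_angular_velocity(4.0, fps=32.0)
        assert rad_per_min == pytest.approx(4 * 32 * 60 * np.pi / 180)
        assert round(rad_per_min) == 134

    def test_zero_amplitude(self):
        assert to_angular_velocity(0.0, fps=32.0) == (0.0, 0.0)

    def test_rpm_arithmetic(self):
        _, rpm = to_angular_velocity(6.0, fps=60.0)
        assert rpm == pytest.approx(60.0)

    def test_invalid_fps(self):
        with pytest.raises(ValueError):
            to_angular_velocity(1.0, fps=0.0)


class TestRotationEstimate:
    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError):
            RotationEstimate(axis=np.array([1.0, 1.0, 0.0]), deg_per_frame=1.0,
                             n_valid_pixels=100, residual=0.0)
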