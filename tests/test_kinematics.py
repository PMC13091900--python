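"""Euler decomposition, pressure maps, COP, MAE stats, marker filtering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pedsim.kinematics import (
    KinematicsError,
    center_of_pressure,
    compose_yxz,
    euler_yxz,
    joint_angles,
    lowpass_markers,
    mae_sd,
    pressure_map,
)


class TestEulerYXZ:
    def test_identity(self):
        e = euler_yxz(np.eye(3))
        assert e.about_y == e.about_x == e.about_z == 0.0

    def test_single_axis_rotations(self):
        for angle, axis_attr in ((10.0, "about_y"), (-25.0, "about_x"),
                                 (40.0, "about_z")):
            axis = {"about_y": "y", "about_x": "x", "about_z": "z"}[axis_attr]
            R = Rotation.from_euler(axis, angle, degrees=True).as_matrix()
            e = euler_yxz(R)
            assert getattr(e, axis_attr) == pytest.approx(angle, abs=1e-9)
            others = {"about_y", "about_x", "about_z"} - {axis_attr}
            for o in others:
                assert getattr(e, o) == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_random_rotations(self, rng):
        for _ in range(1000):
            R = Rotation.random(random_state=int(rng.integers(2**31))
                                ).as_matrix()
            e = euler_yxz(R)
            back = compose_yxz(e.about_y, e.about_x, e.about_z)
            assert np.linalg.norm(back - R) < 1e-9

    def test_composition_order_is_y_then_x_then_z(self):
        R = compose_yxz(10.0, 20.0, 30.0)
        expected = (Rotation.from_euler("y", 10, degrees=True).as_matrix()
                    @ Rotation.from_euler("x", 20, degrees=True).as_matrix()
                    @ Rotation.from_euler("z", 30, degrees=True).as_matrix())
        assert np.allclose(R, expected, atol=1e-12)

    def test_gimbal_proximity_flagged(self):
        R = compose_yxz(10.0, 89.7, 5.0)
        assert euler_yxz(R).gimbal_proximity

    def test_rejects_non_rotation(self):
        with pytest.raises(KinematicsError):
            euler_yxz(np.eye(3) * 2.0)
        with pytest.raises(KinematicsError):
            euler_yxz(np.diag([1.0, 1.0, -1.0]))


class TestJointAngles:
    def test_reference_posture_is_zero(self):
        Rp = Rotation.random(random_state=1).as_matrix()
        Rd = Rotation.random(random_state=2).as_matrix()
        e = joint_angles(Rp, Rd, Rp, Rd)
        assert np.allclose(e.as_array(), 0.0, atol=1e-9)

    def test_distal_rotation_about_proximal_y(self):
        Rp = np.eye(3)
        Rd = Rotation.from_euler("y", 5.0, degrees=True).as_matrix()
        e = joint_angles(Rp, Rd, np.eye(3), np.eye(3))
        assert e.about_y == pytest.approx(5.0, abs=1e-9)
        assert abs(e.about_x) < 1e-9 and abs(e.about_z) < 1e-9

    def test_invariant_to_common_rotation(self, rng):
        Rp0 = Rotation.random(random_state=3).as_matrix()
        Rd0 = Rotation.random(random_state=4).as_matrix()
        Rrel = Rotation.from_euler("YXZ", [7, -3, 12], degrees=True).as_matrix()
        base = joint_angles(Rp0, Rp0 @ Rrel, Rp0, Rd0)
        for _ in range(20):
            G = Rotation.random(random_state=int(rng.integers(2**31))
                                ).as_matrix()
            moved = joint_angles(G @ Rp0, G @ Rp0 @ Rrel, Rp0, Rd0)
            assert np.allclose(moved.as_array(), base.as_array(), atol=1e-9)

    def test_missing_reference_is_error(self):
        with pytest.raises(KinematicsError):
            joint_angles(np.eye(3), np.eye(3))


class TestPressureMap:
    def test_single_point_pressure(self):
        pm = pressure_map([[5.0, 5.0]], [100.0], origin=(0, 0),
                          cell_size=10.0, shape=(3, 3))
        assert pm.pressure[0, 0] == pytest.approx(1.0)   # 100 N / 100 mm^2
        assert pm.pressure.sum() == pytest.approx(1.0)
        assert np.allclose(pm.cop, [5.0, 5.0])

    def test_force_conservation(self, rng):
        pts = rng.uniform(0, 100, (50, 2))
        f = rng.uniform(0, 10, 50)
        pm = pressure_map(pts, f, origin=(0, 0), cell_size=5.0, shape=(21, 21))
        assert pm.total_force == pytest.approx(f.sum(), rel=1e-9)

    def test_downsample_idempotent_on_uniform_block(self):
        pm = pressure_map([[2, 2], [7, 2], [2, 7], [7, 7]], [25.0] * 4,
                          origin=(0, 0), cell_size=5.0, shape=(2, 2))
        coarse = pm.downsample(2)
        assert coarse.pressure.shape == (1, 1)
        assert coarse.pressure[0, 0] == pytest.approx(1.0)
        assert coarse.total_force == pytest.approx(pm.total_force)

    def test_empty_contact_set(self):
        pm = pressure_map(np.zeros((0, 2)), np.zeros(0), origin=(0, 0),
                          cell_size=5.0, shape=(4, 4))
        assert pm.cop is None
        assert pm.pressure.sum() == 0.0

    def test_uncovered_point_is_error(self):
        with pytest.raises(KinematicsError):
            pressure_map([[200.0, 0.0]], [1.0], origin=(0, 0),
                         cell_size=10.0, shape=(3, 3))


class TestCOP:
    def test_single_point(self):
        assert np.allclose(center_of_pressure([[3.0, 4.0]], [10.0]), [3, 4])

    def test_midpoint_symmetry(self):
        cop = center_of_pressure([[0, 0], [10, 0]], [5.0, 5.0])
        assert np.allclose(cop, [5, 0])

    def test_weighted_mean(self):
        cop = center_of_pressure([[0.0, 0.0], [4.0, 0.0]], [1.0, 3.0])
        assert cop[0] == pytest.approx(3.0)

    def test_zero_force_undefined(self):
        with pytest.raises(KinematicsError):
            center_of_pressure([[0, 0]], [0.0])


class TestMaeSd:
    def test_identical_series(self):
        m, s = mae_sd([1, 2, 3], [1, 2, 3])
        assert m == 0.0 and s == 0.0

    def test_constant_offset(self):
        m, s = mae_sd([1, 2, 3], [4, 5, 6])
        assert m == pytest.approx(3.0) and s == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # |A-B| = {1, 2, 3} -> mean 2, sample SD 1
        m, s = mae_sd([1, 2, 3], [2, 4, 6])
        assert m == pytest.approx(2.0) and s == pytest.approx(1.0)

    def test_symmetry_and_translation_invariance(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        assert mae_sd(a, b) == mae_sd(b, a)
        m1, s1 = mae_sd(a, b)
        m2, s2 = mae_sd(a + 5.0, b + 5.0)
        assert m1 == pytest.approx(m2) and s1 == pytest.approx(s2)


class TestLowpass:
    def test_dc_preserved(self):
        x = np.full(200, 3.3)
        y = lowpass_markers(x, sample_rate=200.0)
        assert np.allclose(y, 3.3, atol=1e-9)

    def test_stopband_attenuation(self):
        t = np.arange(400) / 200.0
        x = np.sin(2 * np.pi * 50.0 * t)
        y = lowpass_markers(x, sample_rate=200.0, cutoff=20.0)
        assert np.abs(y[50:-50]).max() < 0.1 * 1.0

    def test_passband_preserved(self):
        t = np.arange(2000) / 200.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass_markers(x, sample_rate=200.0, cutoff=20.0)
        assert np.abs(y[200:-200] - x[200:-200]).max() < 0.01

    def test_below_nyquist_rejected(self):
        with pytest.raises(KinematicsError):
            lowpass_markers(np.zeros(100), sample_rate=30.0, cutoff=20.0)
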