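import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneeprop.kinematics import (
    AttitudeState,
    DegenerateConfigurationError,
    GaitCycleSequence,
    GimbalLockError,
    InvalidRotationError,
    attitude_from_rotation,
    compose_cardan_zxy,
    enforce_axis_continuity,
    extract_cardan_zxy,
    joint_axes_from_rotation,
    project_attitude,
    relative_rotation,
    rotation_from_attitude,
    validate_rotation,
)
from conftest import random_rotation

Z = np.array([0.0, 0.0, 1.0])


def rz(deg):
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class TestCardan:
    def test_identity_and_z_rotation(self):
        assert np.allclose(compose_cardan_zxy(0, 0, 0), np.eye(3))
        assert np.allclose(compose_cardan_zxy(45, 0, 0), rz(45))

    def test_matrix_structure(self):
        t1, t2, t3 = 30.0, 10.0, 5.0
        R = compose_cardan_zxy(t1, t2, t3)
        validate_rotation(R)
        a, b = np.radians(t1), np.radians(t2)
        assert R[2, 1] == pytest.approx(np.sin(b), abs=1e-12)
        expected_col2 = [-np.sin(a) * np.cos(b), np.cos(a) * np.cos(b), np.sin(b)]
        assert np.allclose(R[:, 1], expected_col2)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(t1=st.floats(-170, 170), t2=st.floats(-88.9, 88.9),
           t3=st.floats(-170, 170))
    def test_round_trip(self, t1, t2, t3):
        out = extract_cardan_zxy(compose_cardan_zxy(t1, t2, t3))
        assert np.allclose(out, (t1, t2, t3), atol=1e-9)

    def test_trivial_extractions(self):
        assert np.allclose(extract_cardan_zxy(np.eye(3)), (0, 0, 0))
        assert np.allclose(extract_cardan_zxy(rz(30)), (30, 0, 0), atol=1e-12)

    def test_gimbal_lock(self):
        with pytest.raises(GimbalLockError):
            extract_cardan_zxy(compose_cardan_zxy(10, 90, 20))

    def test_invalid_matrix_rejected(self):
        with pytest.raises(InvalidRotationError):
            validate_rotation(np.diag([1.0, 1.0, -1.0]))
        with pytest.raises(InvalidRotationError):
            validate_rotation(2 * np.eye(3))


class TestAttitude:
    def test_identity_is_degenerate_with_fallback_axis(self):
        att = attitude_from_rotation(np.eye(3))
        assert att.degenerate
        assert att.theta_deg == 0.0
        assert np.allclose(att.axis, Z)

    def test_z_rotation(self):
        att = attitude_from_rotation(rz(30))
        assert att.theta_deg == pytest.approx(30.0, abs=1e-9)
        assert np.allclose(att.axis, Z)

    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_random(self, seed):
        R = random_rotation(np.random.default_rng(seed))
        att = attitude_from_rotation(R)
        assert 0.0 <= att.theta_deg <= 180.0
        assert np.abs(rotation_from_attitude(att) - R).max() < 1e-8

    @pytest.mark.parametrize("theta", [179.995, 180.0])
    def test_near_half_turn_branch(self, theta):
        axis = np.array([1.0, 2.0, 2.0]) / 3.0
        R = rotation_from_attitude(theta, axis)
        att = attitude_from_rotation(R)
        assert np.abs(rotation_from_attitude(att) - R).max() < 1e-8

    def test_rodrigues_against_independent_evaluation(self):
        # independently coded Rodrigues: rotate basis vectors explicitly
        theta = np.radians(37.0)
        k = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
        cols = []
        for v in np.eye(3):
            cols.append(v * np.cos(theta) + np.cross(k, v) * np.sin(theta)
                        + k * (k @ v) * (1 - np.cos(theta)))
        expected = np.stack(cols, axis=1)
        assert np.allclose(rotation_from_attitude(37.0, k), expected, atol=1e-12)

    def test_zero_angle_gives_identity(self):
        assert np.allclose(rotation_from_attitude(0.0, np.array([1.0, 0, 0])),
                           np.eye(3))
        assert np.allclose(rotation_from_attitude(90.0, Z), rz(90))

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError):
            rotation_from_attitude(10.0, np.array([1.0, 1.0, 0.0]))
        with pytest.raises(ValueError):
            AttitudeState(10.0, np.array([0.0, 0.0, 2.0]))


class TestJointAxes:
    def test_identity_pose(self):
        ax = joint_axes_from_rotation(np.eye(3))
        assert np.allclose(ax.e1, Z)
        assert np.allclose(ax.e3, [0, 1, 0])
        assert np.allclose(ax.e2, [1, 0, 0])

    def test_hand_evaluated_at_60deg(self):
        ax = joint_axes_from_rotation(rz(60))
        assert np.allclose(ax.e3, [-np.sin(np.radians(60)), 0.5, 0.0])
        assert np.allclose(ax.e2, [0.5, np.sin(np.radians(60)), 0.0])

    def test_floating_axis_orthogonality(self):
        R = compose_cardan_zxy(40, 8, -6)
        ax = joint_axes_from_rotation(R)
        assert abs(ax.e2 @ ax.e1) < 1e-12
        assert abs(ax.e2 @ ax.e3) < 1e-12
        assert abs(ax.mixed_product) > 1e-3

    def test_degenerate_when_shank_axis_hits_flexion_axis(self):
        # ZXY with second angle 90 deg sends the shank Y axis to thigh Z
        R = compose_cardan_zxy(0, 90, 0)
        with pytest.raises(DegenerateConfigurationError):
            joint_axes_from_rotation(R)


class TestProjection:
    def test_hinge_identity(self):
        R = rz(60)
        att = attitude_from_rotation(R)
        proj = project_attitude(att, joint_axes_from_rotation(R))
        assert np.allclose(proj, (60, 0, 0), atol=1e-9)
        assert np.allclose(extract_cardan_zxy(R), (60, 0, 0), atol=1e-9)

    def test_zero_angle_projects_to_zero(self):
        axes = joint_axes_from_rotation(compose_cardan_zxy(25, 5, 5))
        att = AttitudeState(0.0, Z, degenerate=True)
        assert np.allclose(project_attitude(att, axes), (0, 0, 0))

    @pytest.mark.parametrize("seed", range(6))
    def test_decomposition_identity(self, seed):
        rng = np.random.default_rng(seed)
        R = random_rotation(rng, theta_range=(5.0, 80.0))
        att = attitude_from_rotation(R)
        axes = joint_axes_from_rotation(R)
        proj = project_attitude(att, axes)
        recomposed = (proj.theta1 * axes.e1 + proj.theta2 * axes.e2
                      + proj.theta3 * axes.e3)
        assert np.allclose(recomposed, att.theta_deg * att.axis, atol=1e-9)

    def test_orthonormal_axes_reduce_to_dot_products(self):
        from kneeprop.kinematics import JointAxesFrame

        axes = JointAxesFrame(Z, np.array([1.0, 0, 0]), np.array([0.0, 1, 0]))
        k = np.array([0.1, 0.2, np.sqrt(1 - 0.05)])
        att = AttitudeState(20.0, k)
        proj = project_attitude(att, axes)
        assert proj.theta1 == pytest.approx(20 * (k @ axes.e1), abs=1e-12)
        assert proj.theta2 == pytest.approx(20 * (k @ axes.e2), abs=1e-12)
        assert proj.theta3 == pytest.approx(20 * (k @ axes.e3), abs=1e-12)

    def test_projection_and_cardan_agree_to_first_order(self):
        # the two descriptions coincide to first order: on a hinge they are
        # identical, and the difference shrinks linearly with the
        # off-flexion offsets (it behaves like flexion x offset)
        from kneeprop.synthetic import GeneratorConfig, template_knee_cycle

        def max_diff(varus, rot):
            tpl = template_knee_cycle(GeneratorConfig(
                varus_offset_deg=varus, rotation_offset_deg=rot))
            return np.abs(tpl.projected_angles() - tpl.cardan_angles()).max()

        assert max_diff(0.0, 0.0) < 1e-9
        full, half = max_diff(2.0, 5.0), max_diff(1.0, 2.5)
        assert 0.35 < half / full < 0.65
        assert max_diff(0.2, 0.5) < 0.25


class TestRelativeRotation:
    def test_equal_orientations_give_identity(self):
        T = random_rotation(np.random.default_rng(3))
        assert np.allclose(relative_rotation(T, T), np.eye(3), atol=1e-12)

    def test_identity_thigh_passes_shank_through(self):
        S = rz(25)
        assert np.allclose(relative_rotation(np.eye(3), S), S)

    def test_dot_product_table_oracle(self):
        rng = np.random.default_rng(11)
        T, S = random_rotation(rng), random_rotation(rng)
        R = relative_rotation(T, S)
        # entry (i, j): j-th shank axis dotted with i-th thigh axis
        expected = np.array([[S[:, j] @ T[:, i] for j in range(3)]
                             for i in range(3)])
        assert np.allclose(R, expected, atol=1e-12)


class TestContinuity:
    def test_uniform_axis_unchanged(self):
        theta = np.full(5, 20.0)
        k = np.tile(Z, (5, 1))
        t2, k2 = enforce_axis_continuity(theta, k, np.zeros(5, bool))
        assert np.allclose(t2, theta) and np.allclose(k2, k)

    def test_sign_flip_preserves_attitude_vector(self):
        theta = np.array([20.0, -20.0, 20.0])
        k = np.array([Z, -Z, Z])
        t2, k2 = enforce_axis_continuity(theta, k, np.zeros(3, bool))
        assert np.all(np.einsum("ij,ij->i", k2[:-1], k2[1:]) > 0)
        assert np.allclose(t2[:, None] * k2, theta[:, None] * k)

    def test_degenerate_frame_interpolated_from_neighbours(self):
        angles = [10.0, 5.0, 0.0, 5.0, 10.0]
        R = np.stack([rz(a) for a in angles])
        theta = np.empty(5)
        k = np.empty((5, 3))
        degen = np.empty(5, bool)
        for i, Ri in enumerate(R):
            att = attitude_from_rotation(Ri)
            theta[i], k[i], degen[i] = att.theta_deg, att.axis, att.degenerate
        t2, k2 = enforce_axis_continuity(theta, k, degen)
        assert degen[2]
        assert np.allclose(k2[2], Z)
        assert np.all(np.einsum("ij,ij->i", k2[:-1], k2[1:]) > 0)


class TestGaitCycleSequence:
    def test_requires_101_frames(self):
        with pytest.raises(ValueError):
            GaitCycleSequence(np.stack([np.eye(3)] * 50))

    def test_template_attitudes_are_continuous(self, default_template):
        theta, k, degen = default_template.attitudes()
        assert not degen.any()
        dots = np.einsum("ij,ij->i", k[:-1], k[1:])
        assert np.all(dots > 0)
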