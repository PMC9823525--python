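import numpy as np
import pytest

import skelkin as sk
from skelkin.kinematics import JointRangeWarning, _frame_derivatives
from skelkin.model_io import DegreeOfFreedom

import oracles
from conftest import random_angles, random_rotation, random_scales


class TestRotationPrimitives:
    def test_zero_angle_is_identity(self, rng):
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        np.testing.assert_allclose(sk.axis_angle_matrix(a, 0.0), np.eye(3), atol=1e-15)

    def test_canonical_z_quarter_turn(self):
        R = sk.axis_angle_matrix((0, 0, 1), np.pi / 2)
        np.testing.assert_allclose(R, [[0, -1, 0], [1, 0, 0], [0, 0, 1]], atol=1e-15)

    def test_matches_rodrigues_oracle_on_random_draws(self, rng):
        for _ in range(20):
            a = rng.normal(size=3)
            a /= np.linalg.norm(a)
            t = rng.uniform(-np.pi, np.pi)
            np.testing.assert_allclose(
                sk.axis_angle_matrix(a, t), oracles.rodrigues(a, t), atol=1e-14
            )

    def test_non_unit_axis_is_an_error_not_normalized(self):
        with pytest.raises(ValueError, match="unit"):
            sk.axis_angle_matrix((0, 0, 0.5), 0.3)

    def test_euler_identity_and_single_axis(self):
        np.testing.assert_allclose(sk.euler_to_matrix((0, 0, 0)), np.eye(3), atol=1e-15)
        np.testing.assert_allclose(
            sk.euler_to_matrix((0, 0, np.pi / 2)),
            sk.axis_angle_matrix((0, 0, 1), np.pi / 2),
            atol=1e-15,
        )

    def test_euler_equals_intrinsic_xyz_composition(self, rng):
        for _ in range(20):
            o = rng.uniform(-np.pi, np.pi, 3)
            composed = (
                sk.axis_angle_matrix((1, 0, 0), o[0])
                @ sk.axis_angle_matrix((0, 1, 0), o[1])
                @ sk.axis_angle_matrix((0, 0, 1), o[2])
            )
            np.testing.assert_allclose(sk.euler_to_matrix(o), composed, atol=1e-14)
            np.testing.assert_allclose(sk.euler_to_matrix(o), oracles.euler_xyz(o), atol=1e-12)

    def test_projection_fixes_scaling_and_preserves_rotations(self, rng):
        R = random_rotation(rng)
        np.testing.assert_allclose(sk.project_to_rotation(R), R, atol=1e-10)
        np.testing.assert_allclose(sk.project_to_rotation(2 * np.eye(3)), np.eye(3), atol=1e-12)

    def test_projection_is_closer_than_the_perturbation(self, rng):
        for _ in range(20):
            R = random_rotation(rng)
            M = R + rng.normal(scale=0.08, size=(3, 3))
            P = sk.project_to_rotation(M)
            assert np.linalg.norm(P - R) <= np.linalg.norm(M - R) + 1e-12
            np.testing.assert_allclose(P.T @ P, np.eye(3), atol=1e-10)
            assert np.linalg.det(P) > 0


class TestScaleTranslation:
    @pytest.mark.parametrize(
        "T,bh,b,expected",
        [
            ((0, -0.4, 0), (1, 1, 1), (1, 1, 1), (0, -0.4, 0)),
            ((0.1, 0.2, 0.3), (2, 2, 2), (1, 1, 1), (0.2, 0.4, 0.6)),
            ((0.1, 0.2, 0.3), (1.1, 0.9, 1.0), (1, 1, 1), (0.11, 0.18, 0.30)),
        ],
    )
    def test_elementwise_ratio(self, T, bh, b, expected):
        np.testing.assert_allclose(sk.scale_translation(T, bh, b), expected, atol=1e-15)

    def test_nonpositive_default_scale_rejected(self):
        with pytest.raises(ValueError):
            sk.scale_translation((1, 1, 1), (1, 1, 1), (1, 0, 1))


class TestMotionTransform:
    def test_no_dofs_is_identity(self):
        np.testing.assert_array_equal(sk.motion_transform([], []), np.eye(4))

    def test_single_dof_is_plain_axis_angle(self, rng):
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        d = DegreeOfFreedom("c", a, (-np.pi, np.pi))
        M = sk.motion_transform([d], [0.7])
        np.testing.assert_allclose(M[:3, :3], sk.axis_angle_matrix(a, 0.7), atol=1e-15)
        np.testing.assert_array_equal(M[:3, 3], 0.0)

    def test_three_dofs_match_literal_sequence_oracle(self, rng):
        for _ in range(20):
            axes = rng.normal(size=(3, 3))
            axes /= np.linalg.norm(axes, axis=1, keepdims=True)
            thetas = rng.uniform(-np.pi, np.pi, 3)
            dofs = [DegreeOfFreedom(f"c{i}", axes[i], (-np.pi, np.pi)) for i in range(3)]
            np.testing.assert_allclose(
                sk.motion_transform(dofs, thetas),
                oracles.motion_matrix(axes, thetas),
                atol=1e-13,
            )

    def test_out_of_range_angle_warns_not_errors(self):
        d = DegreeOfFreedom("c", np.array([0.0, 0.0, 1.0]), (-0.5, 0.5))
        with pytest.warns(JointRangeWarning):
            M = sk.motion_transform([d], [1.0])
        assert np.isfinite(M).all()


class TestJointAndChainTransforms:
    def test_joint_frame_identity_and_pure_translation(self):
        np.testing.assert_array_equal(sk.joint_frame_transform((0, 0, 0), (0, 0, 0)), np.eye(4))
        T = sk.joint_frame_transform((0, 0, 0), (1, 2, 3))
        np.testing.assert_array_equal(T[:3, 3], [1, 2, 3])
        np.testing.assert_array_equal(T[:3, :3], np.eye(3))

    def test_joint_frame_action_on_origin_is_translation(self, rng):
        o = rng.uniform(-np.pi, np.pi, 3)
        t = rng.normal(size=3)
        T = sk.joint_frame_transform(o, t)
        np.testing.assert_allclose((T @ [0, 0, 0, 1])[:3], t, atol=1e-15)

    def test_zero_pose_gives_translation_difference(self, planar_arm):
        elbow = planar_arm.joints[1]
        A = sk.parent_child_transform(elbow, [0.0])
        np.testing.assert_allclose(A[:3, 3], elbow.translation_in_parent, atol=1e-15)
        np.testing.assert_allclose(A[:3, :3], np.eye(3), atol=1e-15)

    def test_rotation_only_joint_equals_axis_angle(self, planar_arm):
        shoulder = planar_arm.joints[0]  # zero translations both sides
        A = sk.parent_child_transform(shoulder, [np.pi / 2])
        np.testing.assert_allclose(
            A[:3, :3], sk.axis_angle_matrix((0, 0, 1), np.pi / 2), atol=1e-15
        )
        np.testing.assert_allclose(A[:3, 3], 0.0, atol=1e-15)

    def test_random_joint_matches_literal_equation_oracle(self, default_model, rng):
        for joint in default_model.joints[:6]:
            thetas = rng.uniform(-0.5, 0.5, len(joint.dofs))
            pr = rng.uniform(0.9, 1.1, 3)
            cr = rng.uniform(0.9, 1.1, 3)
            np.testing.assert_allclose(
                sk.parent_child_transform(joint, thetas, pr, cr),
                oracles.parent_child_matrix(joint, thetas, pr, cr),
                atol=1e-13,
            )

    def test_root_transform_zero_angles_identity(self, default_model):
        T = sk.root_transform_from_angles(default_model.root_joint, np.zeros(3))
        np.testing.assert_allclose(T, np.eye(4), atol=1e-15)

    def test_root_transform_matches_oracle_and_is_orthonormal(self, default_model, rng):
        rj = default_model.root_joint
        for _ in range(10):
            q = rng.uniform(-np.pi, np.pi, 3)
            T = sk.root_transform_from_angles(rj, q)
            np.testing.assert_allclose(T, oracles.root_matrix(rj, q), atol=1e-13)
            R = T[:3, :3]
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
            np.testing.assert_array_equal(T[:3, 3], 0.0)


class TestForwardKinematics:
    def test_planar_arm_closed_form(self, planar_arm):
        pose = sk.forward_kinematics(
            planar_arm, None, {"shoulder_angle": np.pi / 2, "elbow_angle": np.pi / 2}
        )
        end = pose.marker_positions[planar_arm.marker_names.index("end")]
        np.testing.assert_allclose(end, [-0.25, 0.3, 0.0], atol=1e-12)

    def test_default_pose_matches_path_product_oracle(self, default_model):
        theta = sk.neutral_angles(default_model)
        pose = sk.forward_kinematics(default_model, None, theta)
        theta_map = dict(zip(default_model.coordinate_names, theta))
        ones = np.ones((len(default_model.bodies), 3))
        markers, joints = oracles.path_product_fk(default_model, ones, theta_map, np.eye(4))
        np.testing.assert_allclose(pose.marker_positions, markers, atol=1e-12)
        for name, p in joints.items():
            np.testing.assert_allclose(
                pose.joint_positions[pose.joint_names.index(name)], p, atol=1e-12
            )

    def test_uniform_scale_linearity(self, default_model, rng):
        theta = random_angles(default_model, rng)
        base = sk.forward_kinematics(default_model, None, theta).marker_positions
        for c in (0.5, 1.1, 2.0):
            scaled = sk.forward_kinematics(
                default_model, sk.BodyScales.uniform(default_model, c), theta
            ).marker_positions
            np.testing.assert_allclose(scaled, c * base, rtol=1e-12, atol=1e-15)

    def test_equivariance_under_root_rotation(self, default_model, rng):
        theta = random_angles(default_model, rng)
        scales = random_scales(default_model, rng)
        R = random_rotation(rng)
        root = random_rotation(rng)
        a = sk.forward_kinematics(default_model, scales, theta, R @ root).marker_positions
        b = sk.forward_kinematics(default_model, scales, theta, root).marker_positions
        np.testing.assert_allclose(a, b @ R.T, atol=1e-12)

    def test_all_rotation_blocks_are_proper(self, default_model, rng):
        theta = random_angles(default_model, rng)
        pose = sk.forward_kinematics(default_model, random_scales(default_model, rng), theta)
        for T in pose.world_transforms:
            R = T[:3, :3]
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-8)
            assert np.linalg.det(R) > 0

    def test_batch_equals_per_frame(self, default_model, rng):
        F = 5
        thetas = np.stack([random_angles(default_model, rng) for _ in range(F)])
        roots = np.stack([random_rotation(rng) for _ in range(F)])
        scales = random_scales(default_model, rng)
        batch = sk.forward_kinematics_batch(default_model, scales, thetas, roots)
        for f in range(F):
            pose = sk.forward_kinematics(default_model, scales, thetas[f], roots[f])
            np.testing.assert_array_equal(batch.marker_positions[f], pose.marker_positions)
            np.testing.assert_array_equal(batch.joint_positions[f], pose.joint_positions)

    def test_missing_coordinate_value_is_an_error(self, planar_arm):
        with pytest.raises(ValueError, match="missing coordinate"):
            sk.forward_kinematics(planar_arm, None, {"shoulder_angle": 0.0})

    def test_unknown_body_in_scales_is_an_error(self, planar_arm):
        bad = sk.BodyScales(["trunk", "upper", "nonesuch"], np.ones((3, 3)))
        with pytest.raises(Exception):
            sk.forward_kinematics(planar_arm, bad, np.zeros(2))


class TestJacobian:
    def test_single_hinge_marker_speed_equals_radius(self, planar_arm):
        # end marker at radius 0.55 m from the shoulder axis when straight
        J = sk.fk_jacobian(planar_arm, None, np.zeros(2))
        end = planar_arm.marker_names.index("end")
        dp = J[3 * end : 3 * end + 3, 0]
        assert np.linalg.norm(dp) == pytest.approx(0.55, abs=1e-12)

    def test_off_path_derivatives_are_zero(self, default_model, rng):
        theta = random_angles(default_model, rng)
        d = _frame_derivatives(default_model, None, theta)
        # a left-hand marker cannot move with the right knee
        m = default_model.marker_names.index("hand_l_yp")
        c = default_model.coordinate_names.index("knee_flexion_r")
        np.testing.assert_array_equal(d.Jm_theta[m, :, c], 0.0)

    def test_matches_central_finite_differences(self, default_model, rng):
        theta = random_angles(default_model, rng)
        scales = random_scales(default_model, rng)
        J = sk.fk_jacobian(default_model, scales, theta)
        h = 1e-6
        C = len(theta)
        for i in rng.choice(C, size=6, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (
                sk.forward_kinematics(default_model, scales, tp).marker_positions
                - sk.forward_kinematics(default_model, scales, tm).marker_positions
            ).ravel() / (2 * h)
            np.testing.assert_allclose(J[:, i], fd, atol=1e-6)
        B = len(default_model.bodies)
        for b, a in [(0, 0), (3, 1), (B - 1, 2)]:
            vp, vm = scales.values.copy(), scales.values.copy()
            vp[b, a] += h
            vm[b, a] -= h
            names = list(default_model.body_names)
            fd = (
                sk.forward_kinematics(default_model, sk.BodyScales(names, vp), theta).marker_positions
                - sk.forward_kinematics(default_model, sk.BodyScales(names, vm), theta).marker_positions
            ).ravel() / (2 * h)
            np.testing.assert_allclose(J[:, C + 3 * b + a], fd, atol=1e-6)
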