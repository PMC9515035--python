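"""Rigid-transform algebra, landmark registration, Euler angles, pivot calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from spheretrack import (
    DegenerateGeometryError,
    EulerTriple,
    IllConditionedError,
    InputError,
    LandmarkSet,
    RigidTransform,
    apply_transform,
    euler_to_rotation,
    pivot_calibrate,
    rigid_register_landmarks,
    rotation_to_euler,
)
from spheretrack.geometry import transforms_from_csv, transforms_to_csv

from _util import pose_errors, rotation_error_deg


def _quat_rotation(qs):
    q = np.asarray(qs)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


unit_quats = st.tuples(*[st.floats(-1, 1) for _ in range(4)]).filter(
    lambda q: np.linalg.norm(q) > 1e-3
)


class TestRigidTransform:
    def test_identity_apply(self):
        assert np.allclose(apply_transform(RigidTransform.identity(), [1, 2, 3]), [1, 2, 3])

    def test_axis_rotation(self):
        T = RigidTransform.from_rotvec([0, 0, 90])
        assert np.allclose(T.apply([1, 0, 0]), [0, 1, 0], atol=1e-12)

    def test_apply_matches_homogeneous_matrix_oracle(self, rng):
        for _ in range(50):
            T = RigidTransform.random(rng)
            p = rng.normal(0, 100, 3)
            expected = (T.matrix @ np.append(p, 1.0))[:3]
            assert np.allclose(T.apply(p), expected, atol=1e-12)

    def test_composition_associative(self, rng):
        A, B, C = (RigidTransform.random(rng) for _ in range(3))
        p = rng.normal(0, 50, 3)
        assert np.allclose(((A @ B) @ C).apply(p), (A @ (B @ C)).apply(p), atol=1e-9)

    @given(unit_quats)
    def test_compose_with_inverse_is_identity(self, q):
        T = RigidTransform(_quat_rotation(q), np.array([10.0, -20.0, 5.0]))
        I = T @ T.inverse()
        assert np.abs(I.rotation - np.eye(3)).max() < 1e-9
        assert np.abs(I.translation).max() < 1e-9

    def test_rejects_non_orthonormal(self):
        with pytest.raises(InputError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))

    def test_rejects_reflection(self):
        with pytest.raises(InputError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_quat_row_round_trip(self, rng):
        T = RigidTransform.random(rng)
        ts, T2 = RigidTransform.from_quat_row(T.to_quat_row(1.5))
        assert ts == 1.5
        assert T.almost_equal(T2, tol=1e-12)

    def test_json_round_trip(self, rng):
        T = RigidTransform.random(rng)
        T2 = RigidTransform.from_json_dict(T.to_json_dict())
        assert T.almost_equal(T2, tol=1e-12)

    def test_trajectory_csv_round_trip(self, rng, tmp_path):
        ts = [0.0, 0.5, 1.25]
        Ts = [RigidTransform.random(rng) for _ in ts]
        path = tmp_path / "traj.csv"
        transforms_to_csv(path, ts, Ts)
        ts2, Ts2 = transforms_from_csv(path)
        assert np.allclose(ts, ts2)
        for a, b in zip(Ts, Ts2):
            assert a.almost_equal(b, tol=1e-9)


class TestRegistration:
    def test_identity_on_equal_sets(self, rng):
        pts = rng.normal(0, 50, (5, 3))
        T, rms = rigid_register_landmarks(pts, pts)
        assert rms < 1e-9
        assert T.almost_equal(RigidTransform.identity(), tol=1e-9)

    def test_exact_recovery_of_known_transform(self, rng):
        pts = rng.normal(0, 50, (4, 3))
        T0 = RigidTransform.random(rng)
        T, rms = rigid_register_landmarks(pts, T0.apply(pts))
        assert rms < 1e-9
        assert T.almost_equal(T0, tol=1e-9)

    def test_residual_matches_independent_procrustes_oracle(self, rng):
        """Noisy problems: residual agrees with a scipy-based Kabsch oracle."""
        for _ in range(30):
            src = rng.normal(0, 60, (4, 3))
            T0 = RigidTransform.random(rng)
            tgt = T0.apply(src) + rng.normal(0, 0.5, (4, 3))
            T, rms = rigid_register_landmarks(src, tgt)
            # independent oracle: scipy align_vectors on centered clouds
            cs, ct = src.mean(0), tgt.mean(0)
            rot, _ = Rotation.align_vectors(tgt - ct, src - cs)
            R = rot.as_matrix()
            resid = (src - cs) @ R.T + ct - tgt
            rms_oracle = np.sqrt(np.mean(np.sum(resid**2, axis=1)))
            assert abs(rms - rms_oracle) < 1e-9

    def test_invariant_under_common_rigid_motion(self, rng):
        src = rng.normal(0, 60, (4, 3))
        tgt = src + rng.normal(0, 1.0, (4, 3))
        _, rms1 = rigid_register_landmarks(src, tgt)
        B = RigidTransform.random(rng)
        _, rms2 = rigid_register_landmarks(B.apply(src), B.apply(tgt))
        assert abs(rms1 - rms2) < 1e-9

    def test_collinear_source_raises(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            rigid_register_landmarks(src, src + 1.0)

    def test_size_mismatch_raises(self, rng):
        with pytest.raises(InputError):
            rigid_register_landmarks(rng.normal(0, 1, (4, 3)), rng.normal(0, 1, (5, 3)))

    def test_landmark_set_validation(self):
        with pytest.raises(InputError):
            LandmarkSet(np.zeros((2, 3)))


class TestEuler:
    @pytest.mark.parametrize(
        "angles,expected",
        [((0, 0, 0), (0, 0, 0)), ((30, 0, 0), (30, 0, 0)), ((10, -20, 140), (10, -20, 140))],
    )
    def test_known_decompositions(self, angles, expected):
        e = rotation_to_euler(euler_to_rotation(angles))
        assert np.allclose([e.rx, e.ry, e.rz], expected, atol=1e-9)

    @given(unit_quats)
    def test_round_trip_identity_away_from_gimbal_lock(self, q):
        R = _quat_rotation(q)
        e = rotation_to_euler(R)
        if abs(abs(e.ry) - 90) < 1.0:
            return  # near gimbal lock: round trip of the triple is not unique
        assert rotation_error_deg(R, euler_to_rotation(e)) < 1e-9

    def test_gimbal_lock_flagged(self):
        e = rotation_to_euler(euler_to_rotation((0, 90, 0)))
        assert e.gimbal_lock
        # the recomposed rotation still matches even when the triple is degenerate
        assert rotation_error_deg(euler_to_rotation((0, 90, 0)), euler_to_rotation(e)) < 1e-6

    def test_magnitude(self):
        assert EulerTriple(1.0, 2.0, 2.0).magnitude == pytest.approx(3.0)


def _pivot_poses(rng, tip_tool, pivot_world, n=20, noise=0.0):
    poses = []
    for _ in range(n):
        R = Rotation.random(random_state=rng).as_matrix()
        t = pivot_world - R @ tip_tool
        if noise > 0:
            t = t + rng.normal(0, noise, 3)
        poses.append(RigidTransform(R, t))
    return poses


class TestPivotCalibration:
    def test_exact_recovery(self, rng):
        tip = np.array([10.0, 0.0, 50.0])
        pivot = np.array([100.0, -30.0, 400.0])
        res = pivot_calibrate(_pivot_poses(rng, tip, pivot))
        assert np.abs(res.tip_offset - tip).max() < 1e-6
        assert np.abs(res.pivot_point - pivot).max() < 1e-6
        assert res.rms < 1e-9

    def test_pure_translations_ill_conditioned(self, rng):
        R = Rotation.random(random_state=rng).as_matrix()
        poses = [RigidTransform(R, rng.normal(0, 100, 3)) for _ in range(10)]
        with pytest.raises(IllConditionedError):
            pivot_calibrate(poses)

    def test_too_few_poses(self, rng):
        with pytest.raises(InputError):
            pivot_calibrate(_pivot_poses(rng, np.zeros(3), np.zeros(3), n=2))

    def test_noisy_rms_matches_normal_equations_oracle(self, rng):
        tip = np.array([5.0, -2.0, 80.0])
        pivot = np.array([0.0, 0.0, 300.0])
        poses = _pivot_poses(rng, tip, pivot, n=15, noise=0.2)
        res = pivot_calibrate(poses)
        # independent oracle: explicit normal equations
        A = np.zeros((3 * len(poses), 6))
        b = np.zeros(3 * len(poses))
        for i, T in enumerate(poses):
            A[3 * i : 3 * i + 3, :3] = T.rotation
            A[3 * i : 3 * i + 3, 3:] = -np.eye(3)
            b[3 * i : 3 * i + 3] = -T.translation
        x = np.linalg.solve(A.T @ A, A.T @ b)
        resid = (A @ x - b).reshape(-1, 3)
        rms_oracle = np.sqrt(np.mean(np.sum(resid**2, axis=1)))
        assert abs(res.rms - rms_oracle) < 1e-9
        assert np.abs(res.tip_offset - x[:3]).max() < 1e-9
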