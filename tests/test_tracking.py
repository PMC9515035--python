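"""Blob detection, sphere measurement, correspondence, pose estimation, tracking."""

import itertools

import numpy as np
import pytest

from spheretrack import (
    AmbiguousCorrespondenceError,
    BlobParams,
    DepthFrame,
    InsufficientSpheresError,
    MarkerGeometry,
    NoiseModel,
    RigidTransform,
    build_lookup_table,
    default_marker,
    detect_blobs,
    estimate_marker_pose,
    generate_static_experiment,
    match_correspondences,
    measure_sphere,
    render_frame,
    track_sequence,
)
from spheretrack.tracking import TrackerConfig

from _util import pose_errors


def _gaussian_blob(img, cx, cy, sigma=2.0, peak=50000.0):
    gx, gy = np.meshgrid(np.arange(img.shape[1]), np.arange(img.shape[0]))
    img += peak * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sigma**2))


class TestDetectBlobs:
    def test_background_only(self):
        assert detect_blobs(np.full((64, 64), 900.0)) == []

    def test_single_blob_subpixel_center(self):
        img = np.full((256, 256), 800.0)
        _gaussian_blob(img, 100.3, 200.6)
        centers = detect_blobs(img)
        assert len(centers) == 1
        assert np.linalg.norm(centers[0] - [100.3, 200.6]) < 0.05

    def test_four_well_separated_blobs(self):
        img = np.full((256, 256), 800.0)
        for cx, cy in [(40, 40), (200, 50), (60, 210), (190, 190)]:
            _gaussian_blob(img, cx, cy)
        assert len(detect_blobs(img)) == 4

    def test_elongated_component_rejected_by_circularity(self):
        img = np.full((128, 128), 800.0)
        img[60:64, 20:100] = 50000.0  # a 4x80 streak (reflection artifact)
        _gaussian_blob(img, 100, 100)
        centers = detect_blobs(img)
        assert len(centers) == 1
        assert np.linalg.norm(centers[0] - [100, 100]) < 0.1

    def test_area_limits(self):
        img = np.full((128, 128), 800.0)
        img[64, 64] = 60000.0  # single hot pixel below min_area
        assert detect_blobs(img, BlobParams(min_area=4)) == []


def _flat_frame(depth_value, focal=256.0, pp=(256.0, 256.0)):
    L = build_lookup_table(focal, pp)
    depth = np.full(L.shape, float(depth_value))
    frame = DepthFrame(
        depth=depth,
        ab=np.zeros(L.shape),
        world_from_left=RigidTransform.identity(),
        left_from_depth=RigidTransform.identity(),
        timestamp=0.0,
    )
    return frame, L


class TestMeasureSphere:
    def test_on_axis_center_correction(self):
        """Surface at (0,0,500), r=6 -> center (0,0,506)."""
        frame, L = _flat_frame(500.0)
        obs = measure_sphere(np.array([256.0, 256.0]), frame, L, r_s=6.0)
        assert obs.valid
        assert np.allclose(obs.world_surface, [0, 0, 500], atol=1e-9)
        assert np.allclose(obs.world_center, [0, 0, 506], atol=1e-9)

    def test_off_axis_center_correction(self):
        """Surface (300,0,400) (range 500), r=5 -> center (303,0,404)."""
        frame, L = _flat_frame(500.0)
        obs = measure_sphere(np.array([448.0, 256.0]), frame, L, r_s=5.0)
        assert np.allclose(obs.camera_point, [300, 0, 400], atol=1e-9)
        assert np.allclose(obs.world_center, [303, 0, 404], atol=1e-9)

    def test_invalid_depth_marks_observation(self):
        frame, L = _flat_frame(0.0)
        obs = measure_sphere(np.array([100.0, 100.0]), frame, L, r_s=6.0)
        assert not obs.valid

    def test_range_conservation_property(self, rng, identity_rig):
        """Center correction moves every point exactly r_s away from the camera."""
        geom = default_marker()
        pose = RigidTransform.from_rotvec([4, -6, 50], translation=(10.0, 5.0, 550.0))
        noise = NoiseModel(depth_sigma=2.0, ab_sigma=150.0, depth_pixel_sigma=0.5)
        frame, _ = render_frame(geom, pose, identity_rig, noise, rng=rng)
        cam = np.zeros(3)
        for p in detect_blobs(frame.ab):
            obs = measure_sphere(p, frame, identity_rig.lookup, geom.sphere_radius)
            if obs.valid:
                gap = np.linalg.norm(obs.world_center - cam) - np.linalg.norm(obs.world_surface - cam)
                assert abs(gap - geom.sphere_radius) < 1e-6


class TestCorrespondence:
    def test_recovers_permutation_exactly(self, marker, rng):
        T = RigidTransform.random(rng, translation_scale=300.0)
        centers = T.apply(marker.sphere_centers)
        perm = rng.permutation(4)
        corr = match_correspondences(centers[perm], marker)
        assert list(corr.geometry_indices) == [0, 1, 2, 3]
        assert np.allclose(corr.centers, centers, atol=1e-9)
        assert corr.max_mismatch_mm < 1e-9

    def test_spurious_point_discarded_and_agrees_with_brute_force(self, marker, rng):
        T = RigidTransform.random(rng, translation_scale=300.0)
        centers = T.apply(marker.sphere_centers) + rng.normal(0, 0.5, (4, 3))
        spurious = T.apply(np.array([200.0, 150.0, 40.0]))
        cands = np.vstack([centers, spurious[None]])
        order = rng.permutation(5)
        corr = match_correspondences(cands[order], marker)
        matched = cands[order][corr.candidate_indices]
        assert np.allclose(np.sort(matched, axis=0), np.sort(centers, axis=0), atol=1e-9)

        # independent brute force: minimize mean |distance mismatch| over all
        # injective 4-assignments
        D = marker.distance_matrix()
        best_cost, best_map = np.inf, None
        C = cands[order]
        dc = np.linalg.norm(C[:, None] - C[None, :], axis=-1)
        for perm in itertools.permutations(range(5), 4):
            cost = np.mean(
                [abs(dc[perm[a], perm[b]] - D[a, b]) for a in range(4) for b in range(a + 1, 4)]
            )
            if cost < best_cost:
                best_cost, best_map = cost, perm
        assert list(corr.candidate_indices) == list(best_map)

    def test_equal_distance_geometry_is_ambiguous(self):
        # isoceles: two pairwise distances exactly equal -> swapping is ambiguous
        kite = MarkerGeometry(
            np.array([[0, 0, 0], [100, 0, 0], [50, 80, 0], [50, -80, 0]], float),
            uniqueness_tolerance=0.0,
            name="kite",
        )
        centers = kite.sphere_centers + 0.0
        with pytest.raises(AmbiguousCorrespondenceError):
            match_correspondences(centers, kite)

    def test_too_few_centers(self, marker):
        with pytest.raises(InsufficientSpheresError):
            match_correspondences(marker.sphere_centers[:2], marker)

    def test_three_of_four_spheres_still_match(self, marker, rng):
        T = RigidTransform.random(rng, translation_scale=200.0)
        centers = T.apply(marker.sphere_centers)[[0, 2, 3]]
        corr = match_correspondences(centers, marker)
        assert list(corr.geometry_indices) == [0, 2, 3]

    def test_invariant_under_rigid_motion_of_candidates(self, marker, rng):
        centers = marker.sphere_centers + rng.normal(0, 0.3, (4, 3))
        c1 = match_correspondences(centers, marker)
        B = RigidTransform.random(rng)
        c2 = match_correspondences(B.apply(centers), marker)
        assert list(c1.candidate_indices) == list(c2.candidate_indices)
        assert abs(c1.mean_mismatch_mm - c2.mean_mismatch_mm) < 1e-9


class TestPoseEstimation:
    def test_recovers_known_placement(self, marker, rng):
        T0 = RigidTransform.random(rng, translation_scale=400.0)
        corr = match_correspondences(T0.apply(marker.sphere_centers), marker)
        pose = estimate_marker_pose(corr, marker, timestamp=2.0)
        terr, rerr = pose_errors(pose.world_from_marker, T0)
        assert terr < 1e-9 and rerr < 1e-9
        assert pose.n_spheres_used == 4
        assert pose.registration_rms_mm < 1e-9

    def test_identity_placement(self, marker):
        corr = match_correspondences(marker.sphere_centers, marker)
        pose = estimate_marker_pose(corr, marker)
        assert pose.world_from_marker.almost_equal(RigidTransform.identity(), tol=1e-9)


class TestTrackSequence:
    def test_zero_noise_is_exact_inverse_of_simulator(self):
        b = generate_static_experiment(n_poses=3, samples_per_pose=2, noise=NoiseModel.none(), seed=21)
        res = track_sequence(b, b.geometry, b.lookup, TrackerConfig(filter_enabled=False))
        assert res.n_tracked() == len(b)
        for k, rec in enumerate(res.records):
            terr, rerr = pose_errors(rec.pose.world_from_marker, b.true_pose(k))
            assert terr < 1e-6 and rerr < 1e-6

    def test_dropout_gaps_only_where_fewer_than_three_visible(self):
        noise = NoiseModel(depth_sigma=0.5, dropout_prob=0.35)
        b = generate_static_experiment(n_poses=4, samples_per_pose=10, noise=noise, seed=8)
        res = track_sequence(b, b.geometry, b.lookup, TrackerConfig(filter_enabled=False))
        n_visible = b.visible.sum(axis=1)
        for k, rec in enumerate(res.records):
            if n_visible[k] >= 3:
                assert rec.pose is not None, f"frame {k}: {rec.error}"
                assert rec.pose.n_spheres_used == n_visible[k]
            else:
                assert rec.pose is None

    def test_deterministic(self):
        b = generate_static_experiment(n_poses=2, samples_per_pose=2, noise=NoiseModel(depth_sigma=2.0), seed=13)
        r1 = track_sequence(b, b.geometry, b.lookup, TrackerConfig(filter_enabled=True))
        r2 = track_sequence(b, b.geometry, b.lookup, TrackerConfig(filter_enabled=True))
        for a, c in zip(r1.records, r2.records):
            assert (a.pose is None) == (c.pose is None)
            if a.pose:
                assert np.array_equal(
                    a.pose.world_from_marker.matrix, c.pose.world_from_marker.matrix
                )

    def test_dataframe_export(self):
        b = generate_static_experiment(n_poses=2, samples_per_pose=1, noise=NoiseModel.none(), seed=30)
        res = track_sequence(b, b.geometry, b.lookup)
        df = res.to_dataframe()
        assert df.shape[0] == 2
        assert {"timestamp", "tx", "qw", "n_spheres_used"} <= set(df.columns)
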