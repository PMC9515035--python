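"""Synthetic scene generation: rendering, experiment protocols, determinism."""

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pytest

from spheretrack import (
    CameraRig,
    DegenerateGeometryError,
    InputError,
    MarkerGeometry,
    NoiseModel,
    RigidTransform,
    TrajectorySpec,
    build_lookup_table,
    default_camera_rig,
    default_marker,
    generate_dynamic_trajectory,
    generate_static_experiment,
    render_frame,
)
from spheretrack.tracking import detect_blobs


class TestMarkerGeometry:
    def test_default_marker_invariants(self, marker):
        d = np.sort(marker.pairwise_distances())
        assert marker.n_spheres == 4
        assert d[0] > 60.0  # generous sphere spacing
        assert np.diff(d).min() > 15.0  # strongly unique distances
        assert marker.sphere_radius == 6.0

    def test_duplicate_distances_rejected(self):
        square = np.array([[0, 0, 0], [100, 0, 0], [100, 100, 0], [0, 100, 0]], float)
        with pytest.raises(InputError, match="unique"):
            MarkerGeometry(square)

    def test_collinear_rejected(self):
        pts = np.array([[0, 0, 0], [50, 0, 0], [120, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            MarkerGeometry(pts)

    def test_file_round_trip(self, marker, tmp_path):
        path = tmp_path / "marker.txt"
        marker.save(path)
        m2 = MarkerGeometry.load(path)
        assert np.allclose(m2.sphere_centers, marker.sphere_centers)
        assert m2.sphere_radius == marker.sphere_radius
        assert path.read_text().startswith("radius 6.0")


def _on_axis_geometry():
    # one sphere exactly on the optical axis at 500 mm, two companions
    return MarkerGeometry(
        np.array([[0.0, 0.0, 500.0], [90.0, 0.0, 500.0], [0.0, 120.0, 510.0]]),
        sphere_radius=6.0,
        name="test-on-axis",
    )


class TestRenderFrame:
    def test_depth_at_principal_pixel_is_nearest_surface(self, identity_rig):
        """On-axis sphere at 500 mm with r=6 -> depth 494 at the principal pixel."""
        frame, truths = render_frame(
            _on_axis_geometry(), RigidTransform.identity(), identity_rig, NoiseModel.none()
        )
        py, px = 255, 255  # principal point (255.5, 255.5): any adjacent pixel is on the disk
        assert frame.depth[py, px] == pytest.approx(494.0, abs=1e-9)
        assert all(t.visible for t in truths)

    def test_curved_shading_close_to_flat_at_center(self, identity_rig):
        frame, _ = render_frame(
            _on_axis_geometry(), RigidTransform.identity(), identity_rig, NoiseModel.none(), shading="curved"
        )
        # principal pixel sits 0.7 px off the exact center ray, so the curved
        # surface is a fraction of a mm farther than the on-axis 494 mm
        assert frame.depth[255, 255] == pytest.approx(494.0, abs=0.2)

    def test_dropout_removes_all_spheres(self, identity_rig, rng):
        noise = NoiseModel(depth_sigma=0, depth_bias_sigma=0, depth_pixel_sigma=0, ab_sigma=0, dropout_prob=0.999999)
        frame, truths = render_frame(
            _on_axis_geometry(), RigidTransform.identity(), identity_rig, noise, rng=rng
        )
        assert frame.ab.max() == noise.ab_background
        assert not any(t.visible for t in truths)
        assert detect_blobs(frame.ab) == []

    def test_sphere_behind_camera_excluded_not_raised(self, identity_rig):
        geom = MarkerGeometry(
            np.array([[0.0, 0.0, -300.0], [90.0, 0.0, 500.0], [0.0, 120.0, 510.0]]),
            name="one-behind",
        )
        frame, truths = render_frame(geom, RigidTransform.identity(), identity_rig, NoiseModel.none())
        reasons = {t.index: t.reason for t in truths if not t.visible}
        assert reasons == {0: "behind"}

    def test_blob_centroids_match_projected_centers(self, identity_rig):
        """Zero noise: detected centroids within 0.5 px of analytic projections."""
        geom = default_marker()
        pose = RigidTransform.from_rotvec([5, -8, 30], translation=(20.0, -15.0, 600.0))
        frame, truths = render_frame(geom, pose, identity_rig, NoiseModel.none())
        centers = detect_blobs(frame.ab)
        assert len(centers) == 4
        for t in truths:
            best = min(np.linalg.norm(c - t.pixel) for c in centers)
            assert best < 0.5

    def test_depth_at_blob_center_equals_range_minus_radius(self, identity_rig):
        geom = default_marker()
        pose = RigidTransform.from_rotvec([0, 0, 70], translation=(-30.0, 10.0, 450.0))
        frame, truths = render_frame(geom, pose, identity_rig, NoiseModel.none())
        for t in truths:
            px = np.round(t.pixel).astype(int)
            assert frame.depth[px[1], px[0]] == pytest.approx(t.range_mm - geom.sphere_radius, abs=1e-9)


class TestStaticExperiment:
    def test_protocol_shape(self):
        b = generate_static_experiment(n_poses=20, samples_per_pose=30, noise=NoiseModel.none(), seed=2)
        assert len(b) == 600
        assert b.truth["pose_index"].nunique() == 20
        assert (np.diff(b.truth["timestamp"]) > 0).all()
        # distances cover the requested range
        d = b.truth.groupby("pose_index")["distance_mm"].first()
        assert d.min() < 450 and d.max() > 850

    def test_needs_at_least_two_poses(self):
        with pytest.raises(InputError):
            generate_static_experiment(n_poses=1)

    def test_deterministic_and_byte_identical_on_disk(self, tmp_path):
        def digest(root: Path) -> str:
            h = hashlib.sha256()
            for f in sorted(root.rglob("*")):
                if f.is_file():
                    h.update(f.name.encode())
                    h.update(f.read_bytes())
            return h.hexdigest()

        for sub in ("a", "b"):
            bundle = generate_static_experiment(
                n_poses=2, samples_per_pose=2, noise=NoiseModel(depth_sigma=2.0), seed=9
            )
            bundle.save(tmp_path / sub)
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_bias_constant_within_pose(self):
        b = generate_static_experiment(n_poses=3, samples_per_pose=4, seed=1)
        # sphere offsets = common(frame) + indiv(frame) + bias(pose): subtracting
        # the per-frame mean leaves pose-correlated structure, checked indirectly
        # via the generator arrays themselves
        assert b.sphere_offsets.shape == (12, 4)
        assert b.visible.all()


class TestDynamicTrajectory:
    def test_pure_sinusoid_frames_and_amplitude(self):
        spec = TrajectorySpec(mode="sinusoid", duration_s=10.0, frame_rate=45.0, lead_amplitude_mm=50.0)
        b = generate_dynamic_trajectory(spec=spec, noise=NoiseModel.none(), seed=3)
        assert len(b) == 450
        x = b.truth["tx"].to_numpy()
        rel = x - x.mean()
        assert np.abs(rel).max() == pytest.approx(50.0, abs=0.15)

    def test_zero_amplitude_is_static(self):
        spec = TrajectorySpec(mode="sinusoid", duration_s=2.0, lead_amplitude_mm=0.0)
        b = generate_dynamic_trajectory(spec=spec, noise=NoiseModel.none(), seed=3)
        assert b.truth[["tx", "ty", "tz"]].std().max() < 1e-12

    def test_velocities_match_finite_differences(self):
        spec = TrajectorySpec()
        h = 1e-5
        for t in (0.5, 3.9, 4.7, 9.3):
            fd = (
                spec.pose_at(t + h).translation - spec.pose_at(t - h).translation
            ) / (2 * h)
            assert np.allclose(spec.velocity_at(t), fd, atol=1e-4)

    def test_rotation_stays_limited_about_x_and_y(self):
        spec = TrajectorySpec()
        from spheretrack import rotation_to_euler

        for t in np.linspace(0, spec.duration_s, 200):
            e = rotation_to_euler(spec.pose_at(t).rotation)
            assert abs(e.rx) <= spec.rot_amplitude_deg[0] + 1e-6
            assert abs(e.ry) <= spec.rot_amplitude_deg[1] + 1e-6

    def test_nyquist_warning(self):
        with pytest.warns(UserWarning, match="Nyquist"):
            TrajectorySpec(frame_rate=10.0, lead_frequency_hz=8.0)

    def test_clock_offset_in_truth(self):
        b = generate_dynamic_trajectory(
            spec=TrajectorySpec(duration_s=2.0), noise=NoiseModel.none(), seed=0, clock_offset_s=0.25
        )
        assert np.allclose(b.truth["ot_timestamp"] - b.truth["timestamp"], 0.25)


class TestBundlePersistence:
    def test_saved_bundle_contains_truth_and_marker(self, tmp_path):
        b = generate_static_experiment(n_poses=2, samples_per_pose=1, noise=NoiseModel.none(), seed=4)
        b.save(tmp_path / "bundle")
        assert (tmp_path / "bundle" / "truth.csv").exists()
        assert (tmp_path / "bundle" / "marker.txt").exists()
        assert (tmp_path / "bundle" / "bundle.json").exists()
        assert (tmp_path / "bundle" / "frame_000000_depth.png").exists()
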