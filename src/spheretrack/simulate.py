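"""Synthetic depth-camera scenes: marker geometries, frame rendering, experiments.

This module stands in for the AR-headset sensor stack.  It renders the two
images the tracker consumes — an active-brightness (AB) image in which each
retroreflective sphere appears as a bright, radially symmetric blob, and a
depth image holding range-along-ray values inside each sphere's silhouette —
and generates the experiment protocols used for evaluation: a static
multi-pose acquisition, a dynamic sinusoidal trajectory with a leading
pure-sinusoid segment for temporal calibration, and stylus scenes for the
ultrasound spatial calibration.

Rendering model
---------------
* AB blobs are Gaussian intensity profiles centered on the exact projection
  of the sphere center (IR bloom of a retroreflector), with width tied to the
  projected silhouette radius.  No IR radiometry: the tracker only needs
  detectable, localizable blobs.
* By default (``shading="flat"``) each sphere's depth disk holds the constant
  range ``||camera -> center|| - r_s``: the exact nearest-surface range on the
  central ray, which is the only depth the tracker ever samples.  This keeps
  the zero-noise pipeline algebraically invertible.  ``shading="curved"``
  renders the physical per-pixel ray/sphere nearest-intersection instead.
* Depth noise decomposes into a per-frame common-mode term shared by all
  spheres (global time-of-flight error), a per-sphere i.i.d. term, a
  per-(pose, sphere) systematic bias (lookup-table miscalibration), and
  per-pixel noise.  The headset's self-localization drift is *not* modelled:
  ``world_from_left`` is exact.

All generators are bit-reproducible given their configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
import warnings
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .bundle import write_frame_bundle
from .calibration import StylusObservation, USImageGeometry
from .camera import CameraRig, DepthFrame, LookupTable, build_lookup_table
from .errors import DegenerateGeometryError, InputError
from .geometry import RigidTransform, euler_to_rotation

__all__ = [
    "MarkerGeometry",
    "NoiseModel",
    "TrajectorySpec",
    "SphereTruth",
    "default_marker",
    "default_camera_rig",
    "render_frame",
    "generate_static_experiment",
    "generate_dynamic_trajectory",
    "generate_calibration_dataset",
    "CalibrationScene",
    "SyntheticBundle",
]


# -------------------------------------------------------------------------
# marker geometry
# -------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MarkerGeometry:
    """Rigid body of retroreflective spheres with unique pairwise distances.

    ``sphere_centers`` are mm coordinates in the marker's reference frame RF.
    Unique pairwise distances (minimum gap ``uniqueness_tolerance``) are what
    make the sphere correspondence identifiable from distances alone.
    """

    sphere_centers: np.ndarray
    sphere_radius: float = 6.0
    name: str = "marker"
    uniqueness_tolerance: float = 3.0

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.sphere_centers, dtype=float))
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 3:
            raise InputError(f"marker needs an (N>=3, 3) center array, got {c.shape}")
        if self.sphere_radius <= 0:
            raise InputError("sphere radius must be positive")
        sv = np.linalg.svd(c - c.mean(0), compute_uv=False)
        if sv[1] <= 1e-9 * max(sv[0], 1.0):
            raise DegenerateGeometryError("sphere centers are collinear")
        d = np.sort(self.pairwise_distances())
        if np.diff(d).min() < self.uniqueness_tolerance:
            raise InputError(
                "pairwise sphere distances are not unique: smallest gap "
                f"{np.diff(d).min():.2f} mm < {self.uniqueness_tolerance} mm"
            )
        object.__setattr__(self, "sphere_centers", c)

    @property
    def n_spheres(self) -> int:
        return self.sphere_centers.shape[0]

    def distance_matrix(self) -> np.ndarray:
        c = self.sphere_centers
        return np.linalg.norm(c[:, None] - c[None, :], axis=-1)

    def pairwise_distances(self) -> np.ndarray:
        d = self.distance_matrix()
        return d[np.triu_indices(self.n_spheres, k=1)]

    # plain-text format: header "radius <mm>", then "id x y z" rows
    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"radius {self.sphere_radius}\n")
            for i, p in enumerate(self.sphere_centers):
                fh.write(f"{i} {p[0]} {p[1]} {p[2]}\n")

    @classmethod
    def load(cls, path, name: Optional[str] = None) -> "MarkerGeometry":
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 2 or header[0] != "radius":
                raise InputError(f"marker file {path}: first line must be 'radius <mm>'")
            radius = float(header[1])
            pts = []
            for line in fh:
                tok = line.split()
                if not tok:
                    continue
                if len(tok) != 4:
                    raise InputError(f"marker file {path}: bad row {line!r}")
                pts.append([float(v) for v in tok[1:]])
        return cls(np.asarray(pts), radius, name=name or os.path.basename(str(path)))


def default_marker() -> MarkerGeometry:
    """The packaged 4-sphere rigid body (a documented stand-in geometry).

    Near-planar like typical optical-tracking tools, minimum pairwise center
    distance 61.2 mm and all pairwise-distance gaps >= 15 mm, so distance-based
    correspondence stays unambiguous under several mm of measurement noise.
    """
    pts = np.array(
        [
            [17.5, 43.8, 6.2],
            [-37.5, 68.8, -3.8],
            [47.5, -51.2, 6.2],
            [-27.5, -61.2, -8.8],
        ]
    )
    return MarkerGeometry(pts, sphere_radius=6.0, name="default-4sphere")


# -------------------------------------------------------------------------
# noise model
# -------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Sensor error model for the synthetic camera.

    ``depth_sigma`` (mm) is the sphere-level random depth error per frame; a
    fraction ``depth_common_fraction`` of its *variance* is a per-frame
    common-mode shift applied to every sphere (global time-of-flight error),
    the remainder i.i.d. per sphere.  ``depth_bias_sigma`` draws a systematic
    per-(pose, sphere) offset emulating lookup-table miscalibration; it is not
    reducible by temporal filtering.  ``depth_pixel_sigma`` is per-pixel noise
    inside each depth disk.  Defaults correspond to the 1.5-2.5 mm depth error
    published for this camera class over 0.3-1 m.
    """

    depth_sigma: float = 2.0
    depth_common_fraction: float = 0.85
    depth_bias_sigma: float = 1.0
    depth_pixel_sigma: float = 0.5
    ab_background: float = 800.0
    ab_sphere: float = 58000.0
    ab_sigma: float = 150.0
    pixel_sigma: float = 0.0  # blob-center jitter, px (angular measurement error)
    dropout_prob: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.depth_sigma, self.depth_bias_sigma, self.depth_pixel_sigma, self.ab_sigma, self.pixel_sigma) < 0:
            raise InputError("noise sigmas must be >= 0")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise InputError("dropout_prob must be in [0, 1)")
        if not (0.0 <= self.depth_common_fraction <= 1.0):
            raise InputError("depth_common_fraction must be in [0, 1]")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Perfectly clean sensor (all noise terms zero)."""
        return cls(
            depth_sigma=0.0,
            depth_bias_sigma=0.0,
            depth_pixel_sigma=0.0,
            ab_sigma=0.0,
            pixel_sigma=0.0,
            dropout_prob=0.0,
        )


def default_camera_rig(focal_px: float = 350.0, shape: tuple[int, int] = (512, 512)) -> CameraRig:
    """Static camera: world frame at the device pose at start (identity), plus a
    small, fixed reference-camera-to-depth-camera extrinsic so the transform
    chain is exercised."""
    pp = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
    return CameraRig(
        lookup=build_lookup_table(focal_px, pp, shape),
        world_from_left=RigidTransform.identity(),
        left_from_depth=RigidTransform.from_rotvec([1.5, -1.0, 0.5], translation=(15.0, -8.0, 5.0)),
    )


# -------------------------------------------------------------------------
# frame rendering
# -------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SphereTruth:
    """Per-sphere ground truth emitted alongside a rendered frame."""

    index: int
    visible: bool
    center_world: np.ndarray
    pixel: Optional[np.ndarray]  # exact projection of the center, (x, y)
    range_mm: float
    depth_offset_mm: float  # total sphere-level depth error applied
    reason: str = ""  # why invisible: "", "dropout", "behind", "out-of-frame"


def _blob_sigma_px(focal_px: float, z_mm: float, r_s: float) -> float:
    sil = focal_px * r_s / max(z_mm, 1e-6)
    return float(np.clip(0.35 * sil, 1.0, 5.0))


def _draw_sphere_noise(noise: NoiseModel, rng: np.random.Generator, n: int):
    cf = noise.depth_common_fraction
    common = rng.normal(0.0, noise.depth_sigma * math.sqrt(cf))
    indiv = rng.normal(0.0, noise.depth_sigma * math.sqrt(1.0 - cf), n)
    jitter = rng.normal(0.0, noise.pixel_sigma, (n, 2))
    visible = rng.random(n) >= noise.dropout_prob
    return common + indiv, jitter, visible


def render_frame(
    geometry: MarkerGeometry,
    marker_pose: RigidTransform,
    rig: CameraRig,
    noise: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
    timestamp: float = 0.0,
    shading: str = "flat",
    sphere_depth_offsets: Optional[np.ndarray] = None,
    sphere_pixel_jitter: Optional[np.ndarray] = None,
    visible_mask: Optional[np.ndarray] = None,
) -> tuple[DepthFrame, list[SphereTruth]]:
    """Render one synthetic depth/AB frame of the marker.

    Sphere-level noise can be passed explicitly (the experiment generators do
    this to keep biases constant within a pose); if omitted it is drawn from
    ``rng`` according to ``noise``.  Spheres behind the camera or projecting
    outside the image are excluded and reported in the truth list, not raised.
    """
    noise = noise or NoiseModel.none()
    rng = rng if rng is not None else np.random.default_rng(noise.seed or 0)
    if shading not in ("flat", "curved"):
        raise InputError(f"unknown shading {shading!r}")

    L = rig.lookup
    h, w = L.shape
    f = L.focal_px
    cx, cy = L.principal_point
    r_s = geometry.sphere_radius
    n = geometry.n_spheres

    offs, jit, vis = _draw_sphere_noise(noise, rng, n)
    if sphere_depth_offsets is not None:
        offs = np.asarray(sphere_depth_offsets, float)
    if sphere_pixel_jitter is not None:
        jit = np.asarray(sphere_pixel_jitter, float)
    if visible_mask is not None:
        vis = np.asarray(visible_mask, bool)

    depth = np.zeros((h, w))
    if noise.ab_sigma > 0:
        ab = rng.normal(noise.ab_background, noise.ab_sigma, (h, w))
    else:
        ab = np.full((h, w), float(noise.ab_background))

    centers_world = marker_pose.apply(geometry.sphere_centers)
    centers_cam = rig.world_from_depth.inverse().apply(centers_world)

    truths: list[SphereTruth] = []
    for i in range(n):
        c = centers_cam[i]
        Z = c[2]
        rng_c = float(np.linalg.norm(c))
        if Z <= r_s or rng_c <= r_s:
            truths.append(SphereTruth(i, False, centers_world[i], None, rng_c, 0.0, "behind"))
            continue
        proj = np.array([cx + f * c[0] / Z, cy + f * c[1] / Z])
        if not (0 <= proj[0] <= w - 1 and 0 <= proj[1] <= h - 1):
            truths.append(SphereTruth(i, False, centers_world[i], proj, rng_c, 0.0, "out-of-frame"))
            continue
        if not vis[i]:
            truths.append(SphereTruth(i, False, centers_world[i], proj, rng_c, 0.0, "dropout"))
            continue

        # --- depth disk -------------------------------------------------
        hw_d = int(math.ceil(1.3 * f * r_s / max(Z - r_s, 1.0))) + 4
        x0, x1 = max(int(proj[0]) - hw_d, 0), min(int(proj[0]) + hw_d, w - 1)
        y0, y1 = max(int(proj[1]) - hw_d, 0), min(int(proj[1]) + hw_d, h - 1)
        dirs = L.entries[y0 : y1 + 1, x0 : x1 + 1]
        b = dirs @ c
        disc = b * b - (c @ c - r_s * r_s)
        mask = (disc >= 0.0) & (b > 0.0)
        if shading == "flat":
            core = np.full(mask.shape, rng_c - r_s + offs[i])
            mask = ndimage.binary_dilation(mask, iterations=2)
        else:
            core = np.zeros(mask.shape)
            core[mask] = b[mask] - np.sqrt(np.maximum(disc[mask], 0.0)) + offs[i]
        if noise.depth_pixel_sigma > 0:
            core = core + rng.normal(0.0, noise.depth_pixel_sigma, core.shape)
        vals = np.maximum(core, 1e-3)
        patch = depth[y0 : y1 + 1, x0 : x1 + 1]
        write = mask & ((patch == 0.0) | (vals < patch))
        patch[write] = vals[write]

        # --- AB blob ----------------------------------------------------
        pb = proj + jit[i]
        sig = _blob_sigma_px(f, Z, r_s)
        hw_a = int(math.ceil(7.0 * sig + 2.0))
        ax0, ax1 = max(int(pb[0]) - hw_a, 0), min(int(pb[0]) + hw_a, w - 1)
        ay0, ay1 = max(int(pb[1]) - hw_a, 0), min(int(pb[1]) + hw_a, h - 1)
        gx, gy = np.meshgrid(np.arange(ax0, ax1 + 1), np.arange(ay0, ay1 + 1))
        rr2 = (gx - pb[0]) ** 2 + (gy - pb[1]) ** 2
        blob = noise.ab_sphere * np.exp(-rr2 / (2.0 * sig * sig))
        blob[rr2 > (7.0 * sig) ** 2] = 0.0  # compact support
        ab[ay0 : ay1 + 1, ax0 : ax1 + 1] += blob

        truths.append(SphereTruth(i, True, centers_world[i], proj, rng_c, float(offs[i])))

    np.clip(ab, 0.0, 65535.0, out=ab)
    frame = DepthFrame(
        depth=depth,
        ab=ab,
        world_from_left=rig.world_from_left,
        left_from_depth=rig.left_from_depth,
        timestamp=timestamp,
    )
    return frame, truths


# -------------------------------------------------------------------------
# lazy synthetic bundles
# -------------------------------------------------------------------------


class SyntheticBundle:
    """A deterministic, lazily rendered frame sequence plus ground truth.

    Frames are regenerated on every iteration from (config, seed), so the
    bundle stays cheap to hold in memory; ``save`` materializes it to a disk
    bundle (quantizing images to 16 bit).  ``truth`` is a DataFrame with one
    row per frame: timestamp, pose (quaternion row), per-sphere true centers
    and visibility, plus generator-specific columns.
    """

    def __init__(
        self,
        rig: CameraRig,
        geometry: MarkerGeometry,
        noise: NoiseModel,
        seed: int,
        timestamps: np.ndarray,
        poses: list[RigidTransform],
        sphere_offsets: np.ndarray,  # (n_frames, n_spheres) total sphere-level depth error
        pixel_jitter: np.ndarray,  # (n_frames, n_spheres, 2)
        visible: np.ndarray,  # (n_frames, n_spheres) bool
        config: dict,
        shading: str = "flat",
        extra_columns: Optional[dict] = None,
    ):
        import pandas as pd

        self.rig = rig
        self.geometry = geometry
        self.noise = noise
        self.seed = int(seed)
        self.timestamps = np.asarray(timestamps, float)
        self.poses = poses
        self.sphere_offsets = sphere_offsets
        self.pixel_jitter = pixel_jitter
        self.visible = visible
        self.config = dict(config)
        self.shading = shading

        cam = rig.center_world
        rows = []
        for k in range(len(poses)):
            row = {"frame": k, "timestamp": self.timestamps[k]}
            ts_row = poses[k].to_quat_row(self.timestamps[k])
            for name, v in zip(("tx", "ty", "tz", "qw", "qx", "qy", "qz"), ts_row[1:]):
                row[name] = v
            centers = poses[k].apply(geometry.sphere_centers)
            for i in range(geometry.n_spheres):
                row[f"s{i}_x"], row[f"s{i}_y"], row[f"s{i}_z"] = centers[i]
                row[f"s{i}_visible"] = bool(visible[k, i])
            row["distance_mm"] = float(np.linalg.norm(poses[k].translation - cam))
            rows.append(row)
        self.truth = pd.DataFrame(rows)
        if extra_columns:
            for name, values in extra_columns.items():
                self.truth[name] = values

    # -- frame access -----------------------------------------------------
    @property
    def lookup(self) -> LookupTable:
        return self.rig.lookup

    def __len__(self) -> int:
        return len(self.poses)

    def frame(self, k: int) -> tuple[DepthFrame, list[SphereTruth]]:
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 7001, k)))
        return render_frame(
            self.geometry,
            self.poses[k],
            self.rig,
            noise=self.noise,
            rng=rng,
            timestamp=float(self.timestamps[k]),
            shading=self.shading,
            sphere_depth_offsets=self.sphere_offsets[k],
            sphere_pixel_jitter=self.pixel_jitter[k],
            visible_mask=self.visible[k],
        )

    def __iter__(self):
        for k in range(len(self)):
            yield self.frame(k)[0]

    def true_pose(self, k: int) -> RigidTransform:
        return self.poses[k]

    # -- persistence ------------------------------------------------------
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.config, sort_keys=True).encode()).hexdigest()[:16]

    def save(self, path, depth_unit_mm: float = 1.0) -> None:
        os.makedirs(path, exist_ok=True)
        write_frame_bundle(
            list(self),
            path,
            lookup=self.rig.lookup,
            depth_unit_mm=depth_unit_mm,
            extra_meta={"seed": self.seed, "config_sha256": self.config_hash(), "config": self.config},
        )
        self.truth.to_csv(os.path.join(path, "truth.csv"), index=False)
        self.geometry.save(os.path.join(path, "marker.txt"))


# -------------------------------------------------------------------------
# static experiment
# -------------------------------------------------------------------------


def _projections_ok(
    centers_cam: np.ndarray, rig: CameraRig, r_s: float, margin_px: float = 30.0
) -> bool:
    """All spheres in front, inside the frustum with margin, blobs separable."""
    L = rig.lookup
    h, w = L.shape
    f, (cx, cy) = L.focal_px, L.principal_point
    z = centers_cam[:, 2]
    if np.any(z < 100.0):
        return False
    proj = np.stack([cx + f * centers_cam[:, 0] / z, cy + f * centers_cam[:, 1] / z], axis=1)
    if np.any(proj[:, 0] < margin_px) or np.any(proj[:, 0] > w - 1 - margin_px):
        return False
    if np.any(proj[:, 1] < margin_px) or np.any(proj[:, 1] > h - 1 - margin_px):
        return False
    sig = np.array([_blob_sigma_px(f, zi, r_s) for zi in z])
    for i in range(len(proj)):
        for j in range(i + 1, len(proj)):
            if np.linalg.norm(proj[i] - proj[j]) < 7.0 * (sig[i] + sig[j]) + 8.0:
                return False
    return True


def _sample_static_poses(
    geometry: MarkerGeometry,
    rig: CameraRig,
    n_poses: int,
    range_mm: tuple[float, float],
    tilt_deg: float,
    rng: np.random.Generator,
    max_retries: int = 500,
) -> list[RigidTransform]:
    lo, hi = range_mm
    span = hi - lo
    # stratified distances so the whole range is covered, in shuffled order
    zs = lo + (rng.permutation(n_poses) + rng.uniform(0.0, 1.0, n_poses)) * span / n_poses
    world_from_depth = rig.world_from_depth
    half_tan = min(rig.lookup.principal_point) / rig.lookup.focal_px
    poses = []
    for z in zs:
        for attempt in range(max_retries):
            lateral = 0.45 * half_tan * z
            x = rng.uniform(-lateral, lateral)
            y = rng.uniform(-lateral, lateral)
            yaw = rng.uniform(0.0, 360.0)
            tx, ty = rng.uniform(-tilt_deg, tilt_deg, 2)
            R = euler_to_rotation((tx, ty, yaw))
            depth_from_marker = RigidTransform(R, np.array([x, y, z]))
            centers_cam = depth_from_marker.apply(geometry.sphere_centers)
            if _projections_ok(centers_cam, rig, geometry.sphere_radius):
                poses.append(world_from_depth @ depth_from_marker)
                break
        else:
            raise InputError(
                f"could not place marker at distance {z:.0f} mm after {max_retries} tries"
            )
    return poses


def generate_static_experiment(
    geometry: Optional[MarkerGeometry] = None,
    n_poses: int = 20,
    range_mm: tuple[float, float] = (300.0, 1000.0),
    samples_per_pose: int = 30,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    frame_rate: float = 45.0,
    rig: Optional[CameraRig] = None,
    tilt_deg: float = 15.0,
    shading: str = "flat",
) -> SyntheticBundle:
    """Static accuracy protocol: ``n_poses`` marker poses over ``range_mm``
    distance from the camera, ``samples_per_pose`` frames each.

    Defaults reproduce the evaluation protocol this simulator emulates: 20
    poses over 0.3-1.0 m with 30 samples per pose at 45 Hz.  Per-sphere
    systematic depth biases are drawn once per pose (they model calibration
    error, which depends on viewing geometry, not time).
    """
    if n_poses < 2:
        raise InputError("static experiment needs >= 2 poses")
    geometry = geometry or default_marker()
    noise = noise if noise is not None else NoiseModel()
    rig = rig or default_camera_rig()
    rng = np.random.default_rng(seed)

    poses_unique = _sample_static_poses(geometry, rig, n_poses, range_mm, tilt_deg, rng)
    n_frames = n_poses * samples_per_pose
    ns = geometry.n_spheres

    bias = rng.normal(0.0, noise.depth_bias_sigma, (n_poses, ns))
    cf = noise.depth_common_fraction
    common = rng.normal(0.0, noise.depth_sigma * math.sqrt(cf), n_frames)
    indiv = rng.normal(0.0, noise.depth_sigma * math.sqrt(1.0 - cf), (n_frames, ns))
    jitter = rng.normal(0.0, noise.pixel_sigma, (n_frames, ns, 2))
    visible = rng.random((n_frames, ns)) >= noise.dropout_prob

    pose_index = np.repeat(np.arange(n_poses), samples_per_pose)
    poses = [poses_unique[p] for p in pose_index]
    offsets = common[:, None] + indiv + bias[pose_index]
    timestamps = np.arange(n_frames) / frame_rate

    config = {
        "kind": "static",
        "n_poses": n_poses,
        "samples_per_pose": samples_per_pose,
        "range_mm": list(range_mm),
        "frame_rate": frame_rate,
        "tilt_deg": tilt_deg,
        "seed": seed,
        "noise": dataclasses.asdict(noise),
        "marker": geometry.name,
        "shading": shading,
    }
    return SyntheticBundle(
        rig,
        geometry,
        noise,
        seed,
        timestamps,
        poses,
        offsets,
        jitter,
        visible,
        config,
        shading=shading,
        extra_columns={"pose_index": pose_index},
    )


# -------------------------------------------------------------------------
# dynamic trajectory
# -------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class TrajectorySpec:
    """Continuous marker motion for the dynamic protocol.

    ``mode``:
      * ``"sinusoid"``  — pure single-axis sinusoid (x) for the whole duration;
      * ``"composite"`` — a leading pure x-sinusoid segment (used for temporal
        calibration) after which multi-axis translation and limited x/y
        rotation sinusoids ramp in C2-smoothly;
      * ``"static-poses"`` — hold each pose of ``poses`` for equal time.

    Amplitudes are mm / degrees; rotation about x and y is kept small,
    mirroring the line-of-sight constraint of a camera-facing marker.
    """

    mode: str = "composite"
    duration_s: float = 16.0
    frame_rate: float = 45.0
    lead_amplitude_mm: float = 40.0
    lead_frequency_hz: float = 0.5
    lead_duration_s: float = 4.0
    ramp_s: float = 1.5
    amplitude_mm: tuple[float, float, float] = (20.0, 25.0, 60.0)
    frequency_hz: tuple[float, float, float] = (0.7, 0.35, 0.25)
    phase_rad: tuple[float, float, float] = (0.0, 1.0, 2.0)
    rot_amplitude_deg: tuple[float, float, float] = (8.0, 8.0, 25.0)
    rot_frequency_hz: tuple[float, float, float] = (0.30, 0.40, 0.20)
    rot_phase_rad: tuple[float, float, float] = (0.5, 1.5, 2.5)
    base_position_mm: tuple[float, float, float] = (0.0, 0.0, 650.0)
    poses: Optional[Sequence[RigidTransform]] = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise InputError("frame rate must be positive")
        if self.mode not in ("sinusoid", "composite", "static-poses"):
            raise InputError(f"unknown trajectory mode {self.mode!r}")
        if self.mode == "static-poses" and not self.poses:
            raise InputError("static-poses mode needs at least one pose")
        nyq = self.frame_rate / 2.0
        freqs = (self.lead_frequency_hz, *self.frequency_hz, *self.rot_frequency_hz)
        if self.mode != "static-poses" and max(freqs) > nyq:
            warnings.warn(
                f"trajectory frequency {max(freqs)} Hz exceeds Nyquist ({nyq} Hz)",
                stacklevel=2,
            )

    # C2 quintic smoothstep ramp for the composite segment
    def _ramp(self, t: float) -> tuple[float, float]:
        if self.ramp_s <= 0:
            s = 1.0 if t >= self.lead_duration_s else 0.0
            return s, 0.0
        u = (t - self.lead_duration_s) / self.ramp_s
        u = min(max(u, 0.0), 1.0)
        s = u**3 * (6 * u * u - 15 * u + 10)
        ds = (30 * u**4 - 60 * u**3 + 30 * u**2) / self.ramp_s
        return s, ds

    def pose_at(self, t: float) -> RigidTransform:
        if self.mode == "static-poses":
            k = min(int(t * len(self.poses) / max(self.duration_s, 1e-9)), len(self.poses) - 1)
            return self.poses[k]
        base = np.asarray(self.base_position_mm, float)
        tw = 2 * math.pi
        pos = base + np.array([self.lead_amplitude_mm * math.sin(tw * self.lead_frequency_hz * t), 0.0, 0.0])
        euler = np.zeros(3)
        if self.mode == "composite":
            s, _ = self._ramp(t)
            A = np.asarray(self.amplitude_mm)
            F = np.asarray(self.frequency_hz)
            P = np.asarray(self.phase_rad)
            pos = pos + s * A * np.sin(tw * F * t + P)
            rA = np.asarray(self.rot_amplitude_deg)
            rF = np.asarray(self.rot_frequency_hz)
            rP = np.asarray(self.rot_phase_rad)
            euler = s * rA * np.sin(tw * rF * t + rP)
        return RigidTransform(euler_to_rotation(euler), pos)

    def velocity_at(self, t: float) -> np.ndarray:
        """Analytic translational velocity (mm/s) in the depth-camera frame."""
        if self.mode == "static-poses":
            return np.zeros(3)
        tw = 2 * math.pi
        v = np.array(
            [self.lead_amplitude_mm * tw * self.lead_frequency_hz * math.cos(tw * self.lead_frequency_hz * t), 0.0, 0.0]
        )
        if self.mode == "composite":
            s, ds = self._ramp(t)
            A = np.asarray(self.amplitude_mm)
            F = np.asarray(self.frequency_hz)
            P = np.asarray(self.phase_rad)
            v = v + ds * A * np.sin(tw * F * t + P) + s * A * tw * F * np.cos(tw * F * t + P)
        return v


def generate_dynamic_trajectory(
    spec: Optional[TrajectorySpec] = None,
    geometry: Optional[MarkerGeometry] = None,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    rig: Optional[CameraRig] = None,
    clock_offset_s: float = 0.0,
    shading: str = "flat",
) -> SyntheticBundle:
    """Dynamic protocol: continuous motion sampled at the frame rate.

    ``clock_offset_s`` shifts the ground-truth ("reference tracker") clock
    relative to the camera clock; the truth table carries both timestamps so
    temporal alignment can be exercised and verified.  Per-sphere systematic
    biases are drawn once for the whole run.
    """
    spec = spec or TrajectorySpec()
    geometry = geometry or default_marker()
    noise = noise if noise is not None else NoiseModel()
    rig = rig or default_camera_rig()
    rng = np.random.default_rng(seed)

    n_frames = int(round(spec.duration_s * spec.frame_rate))
    timestamps = np.arange(n_frames) / spec.frame_rate
    world_from_depth = rig.world_from_depth
    poses = [world_from_depth @ spec.pose_at(float(t)) for t in timestamps]

    for k, T in enumerate(poses):
        centers_cam = world_from_depth.inverse().apply(T.apply(geometry.sphere_centers))
        if not _projections_ok(centers_cam, rig, geometry.sphere_radius, margin_px=10.0):
            raise InputError(f"trajectory leaves the camera frustum at frame {k}")

    ns = geometry.n_spheres
    bias = rng.normal(0.0, noise.depth_bias_sigma, ns)
    cf = noise.depth_common_fraction
    common = rng.normal(0.0, noise.depth_sigma * math.sqrt(cf), n_frames)
    indiv = rng.normal(0.0, noise.depth_sigma * math.sqrt(1.0 - cf), (n_frames, ns))
    jitter = rng.normal(0.0, noise.pixel_sigma, (n_frames, ns, 2))
    visible = rng.random((n_frames, ns)) >= noise.dropout_prob
    offsets = common[:, None] + indiv + bias[None, :]

    config = {
        "kind": "dynamic",
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(spec).items()
            if k != "poses"
        },
        "seed": seed,
        "clock_offset_s": clock_offset_s,
        "noise": dataclasses.asdict(noise),
        "marker": geometry.name,
        "shading": shading,
    }
    bundle = SyntheticBundle(
        rig,
        geometry,
        noise,
        seed,
        timestamps,
        poses,
        offsets,
        jitter,
        visible,
        config,
        shading=shading,
        extra_columns={"ot_timestamp": timestamps + clock_offset_s},
    )
    bundle.spec = spec
    bundle.clock_offset_s = clock_offset_s
    return bundle


# -------------------------------------------------------------------------
# calibration scenes
# -------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CalibrationScene:
    """Synthetic stylus-calibration data with known ground truth."""

    observations: list[StylusObservation]
    tracker_from_marker: RigidTransform  # static OT_T_M during calibration
    true_marker_from_image: RigidTransform  # ground-truth M_T_US
    image_geometry: USImageGeometry
    seed: int

    @property
    def true_tracker_from_image(self) -> RigidTransform:
        return self.tracker_from_marker @ self.true_marker_from_image


def generate_calibration_dataset(
    image_geometry: Optional[USImageGeometry] = None,
    true_marker_from_image: Optional[RigidTransform] = None,
    n_points: int = 8,
    tip_sigma_mm: float = 0.0,
    pixel_sigma_px: float = 0.0,
    seed: int = 0,
    tracker_from_marker: Optional[RigidTransform] = None,
) -> CalibrationScene:
    """Stylus observations for the spatial-calibration loop.

    ``n_points`` tip positions (default 8) are spread over the US image plane,
    rejected and resampled if near-collinear; tip positions in the tracker
    frame are generated consistently with the ground-truth transforms, with
    optional Gaussian tip noise (mm) and image-identification noise (px).
    """
    if n_points < 3:
        raise InputError("calibration needs at least 3 stylus points")
    rng = np.random.default_rng(seed)
    geom = image_geometry or USImageGeometry()
    if true_marker_from_image is None:
        true_marker_from_image = RigidTransform.random(rng, translation_scale=50.0)
    if tracker_from_marker is None:
        tracker_from_marker = RigidTransform.random(rng, translation_scale=300.0)

    mx = 0.08 * geom.width_px
    my = 0.08 * geom.height_px
    for _ in range(200):
        px = np.column_stack(
            [
                rng.uniform(mx, geom.width_px - 1 - mx, n_points),
                rng.uniform(my, geom.height_px - 1 - my, n_points),
            ]
        )
        sv = np.linalg.svd(px - px.mean(0), compute_uv=False)
        if sv[1] > 0.1 * geom.width_px:
            break
    else:  # pragma: no cover - 200 uniform draws essentially never stay collinear
        raise DegenerateGeometryError("could not sample non-collinear stylus points")

    tracker_from_image = tracker_from_marker @ true_marker_from_image
    img_mm = geom.pixel_to_mm(px)
    trk = tracker_from_image.apply(img_mm)
    if tip_sigma_mm > 0:
        trk = trk + rng.normal(0.0, tip_sigma_mm, trk.shape)
    px_obs = px + (rng.normal(0.0, pixel_sigma_px, px.shape) if pixel_sigma_px > 0 else 0.0)

    obs = [StylusObservation(px_obs[i], trk[i]) for i in range(n_points)]
    return CalibrationScene(obs, tracker_from_marker, true_marker_from_image, geom, seed)
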