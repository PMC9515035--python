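"""The marker-tracking cycle: blobs -> sphere centers -> correspondence -> pose.

Per frame:

1. detect bright sphere blobs in the active-brightness image;
2. back-project each blob center through the depth image and lookup table,
   chain into the world frame, and push the measured *surface* point radially
   away from the camera by the sphere radius to get the *center*;
3. identify which detected center is which marker sphere from the (unique)
   pairwise distance pattern;
4. optionally Kalman-filter each corrected center in world coordinates;
5. landmark-register the marker's reference sphere centers onto the measured
   ones to obtain the 6-DoF pose ``world_from_marker``.

Frames that fail any stage yield a gap (``None`` pose) plus a diagnostic
record — never a fabricated pose.  The whole cycle is deterministic.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Optional

import numpy as np
from skimage import filters as _sk_filters
from skimage import measure as _sk_measure

from .camera import DepthFrame, LookupTable, camera_center
from .errors import (
    AmbiguousCorrespondenceError,
    CorrespondenceError,
    InputError,
    InsufficientSpheresError,
)
from .geometry import RigidTransform, rigid_register_landmarks
from .kalman import KalmanParams, KalmanTrack, kalman_step
from .simulate import MarkerGeometry

__all__ = [
    "BlobParams",
    "SphereObservation",
    "TrackedPose",
    "TrackerConfig",
    "CorrespondenceResult",
    "detect_blobs",
    "measure_sphere",
    "match_correspondences",
    "estimate_marker_pose",
    "track_sequence",
    "TrackingResult",
]


@dataclasses.dataclass(frozen=True)
class BlobParams:
    """Blob-detector settings (all exposed because no published values exist).

    With ``intensity_threshold=None`` the threshold is ``median +
    threshold_fraction * (max - median)`` of the AB image — robust when blobs
    cover a tiny image fraction.  ``use_otsu`` switches to Otsu instead.
    """

    intensity_threshold: Optional[float] = None
    threshold_fraction: float = 0.35
    use_otsu: bool = False
    min_area: int = 4
    max_area: int = 2000
    min_circularity: float = 0.6

    def __post_init__(self) -> None:
        if not (0 < self.min_area < self.max_area):
            raise InputError("need 0 < min_area < max_area")
        if not (0.0 <= self.min_circularity <= 1.0):
            raise InputError("min_circularity must be in [0, 1]")


def detect_blobs(ab: np.ndarray, params: Optional[BlobParams] = None) -> list[np.ndarray]:
    """Subpixel centers ``(x, y)`` of bright circular blobs in an AB image.

    Threshold -> connected components -> area & circularity filter ->
    background-subtracted intensity-weighted centroid over a window around
    each surviving component (other components masked out of the window).
    An empty list is a valid result.  Output order is by image position.
    """
    params = params or BlobParams()
    img = np.asarray(ab, dtype=float)
    if img.ndim != 2:
        raise InputError(f"AB image must be 2-D, got shape {img.shape}")
    bg = float(np.median(img))
    peak = float(img.max())
    if params.intensity_threshold is not None:
        thr = float(params.intensity_threshold)
    elif params.use_otsu:
        if peak <= bg:
            return []
        thr = float(_sk_filters.threshold_otsu(img))
    else:
        if peak <= bg:
            return []
        thr = bg + params.threshold_fraction * (peak - bg)

    labels = _sk_measure.label(img > thr)
    h, w = img.shape
    centers: list[np.ndarray] = []
    for prop in _sk_measure.regionprops(labels):
        if not (params.min_area <= prop.area <= params.max_area):
            continue
        perim = prop.perimeter
        circ = 1.0 if perim <= 0 else 4.0 * np.pi * prop.area / (perim * perim)
        if circ < params.min_circularity:
            continue
        # refined centroid over a window wide enough to capture the blob's
        # tails (component radius r_c ~ 1.45 sigma for the default threshold,
        # window 4.6 r_c ~ 6.7 sigma)
        y0, x0, y1, x1 = prop.bbox
        r_c = max(y1 - y0, x1 - x0) / 2.0
        W = int(np.ceil(4.6 * r_c)) + 2
        cyc, cxc = prop.centroid
        ax0, ax1 = max(int(round(cxc)) - W, 0), min(int(round(cxc)) + W, w - 1)
        ay0, ay1 = max(int(round(cyc)) - W, 0), min(int(round(cyc)) + W, h - 1)
        win = img[ay0 : ay1 + 1, ax0 : ax1 + 1] - bg
        lab_win = labels[ay0 : ay1 + 1, ax0 : ax1 + 1]
        win = np.where((lab_win != 0) & (lab_win != prop.label), 0.0, win)
        total = win.sum()
        if total <= 0:
            continue
        gx, gy = np.meshgrid(np.arange(ax0, ax1 + 1), np.arange(ay0, ay1 + 1))
        centers.append(np.array([(win * gx).sum() / total, (win * gy).sum() / total]))
    centers.sort(key=lambda c: (round(c[1], 3), round(c[0], 3)))
    return centers


@dataclasses.dataclass
class SphereObservation:
    """One sphere measurement through the full back-projection chain."""

    pixel: np.ndarray  # (x, y), subpixel
    depth_mm: float  # range sampled at the blob center
    camera_point: np.ndarray  # D_s, depth-camera frame
    world_surface: np.ndarray  # W_s
    world_center: np.ndarray  # W_s_c (surface-to-center corrected)
    valid: bool = True
    geometry_index: Optional[int] = None


def _sample_depth_bilinear(depth: np.ndarray, p: np.ndarray) -> float:
    """Bilinear depth at subpixel p, ignoring invalid (0) neighbours.

    Returns 0.0 (invalid) if all four neighbours are invalid.
    """
    h, w = depth.shape
    x0 = int(np.floor(p[0]))
    y0 = int(np.floor(p[1]))
    x0 = min(max(x0, 0), w - 2)
    y0 = min(max(y0, 0), h - 2)
    fx, fy = p[0] - x0, p[1] - y0
    vals = depth[y0 : y0 + 2, x0 : x0 + 2]
    wts = np.array([[(1 - fy) * (1 - fx), (1 - fy) * fx], [fy * (1 - fx), fy * fx]])
    valid = vals > 0
    if not valid.any():
        return 0.0
    wsum = wts[valid].sum()
    if wsum <= 0:
        return float(vals[valid][np.argmax(wts[valid])])
    return float((vals[valid] * wts[valid]).sum() / wsum)


def measure_sphere(
    p: np.ndarray, frame: DepthFrame, L: LookupTable, r_s: float
) -> SphereObservation:
    """Measure one sphere center from a detected blob center ``p``.

    Chains back-projection (range times unit ray), the world-frame transform
    chain, and the surface-to-center correction, which pushes the measured
    surface point away from the camera center by the sphere radius:

        center = surface + r_s * (surface - cam) / ||surface - cam||

    An invalid depth sample (0) yields an observation with ``valid=False``
    (feeding a predict-only filter step) rather than an exception.
    """
    p = np.asarray(p, float).reshape(2)
    h, w = L.shape
    if not (0 <= p[0] <= w - 1 and 0 <= p[1] <= h - 1):
        raise InputError(f"blob center {p} outside image")
    d_p = _sample_depth_bilinear(np.asarray(frame.depth, float), p)
    if d_p <= 0:
        return SphereObservation(p, 0.0, np.zeros(3), np.zeros(3), np.zeros(3), valid=False)
    D_s = d_p * L.direction(p)
    W_T_D = frame.world_from_depth
    W_s = W_T_D.apply(D_s)
    cam = camera_center(frame)
    ray = W_s - cam
    W_s_c = W_s + r_s * ray / np.linalg.norm(ray)
    return SphereObservation(p, d_p, D_s, W_s, W_s_c, valid=True)


@dataclasses.dataclass(frozen=True)
class CorrespondenceResult:
    geometry_indices: np.ndarray  # which marker spheres were matched
    candidate_indices: np.ndarray  # which input centers they correspond to
    centers: np.ndarray  # (k, 3) matched centers, ordered by geometry index
    mean_mismatch_mm: float
    max_mismatch_mm: float


_MAX_CANDIDATES = 10


def match_correspondences(
    centers: np.ndarray,
    geometry: MarkerGeometry,
    tol: float = 5.0,
    ambiguity_margin: float = 1.0,
) -> CorrespondenceResult:
    """Identify measured centers with marker spheres by pairwise distances.

    Exhaustively scores every injective assignment of ``k = min(n_candidates,
    n_spheres)`` (down to 3) marker spheres onto candidate centers by the mean
    absolute mismatch against the marker's distance matrix.  The best
    assignment is accepted only if its *max* pair mismatch is within ``tol``
    and the best *conflicting* assignment — one that pairs a shared candidate
    or marker sphere differently — is worse by at least ``ambiguity_margin``
    (mean mismatch); two mutually consistent partial assignments are not
    ambiguous.  Failures raise explicit errors; spurious candidates
    (reflections) are simply left unmatched.
    """
    centers = np.atleast_2d(np.asarray(centers, float))
    n = centers.shape[0]
    m = geometry.n_spheres
    if n < 3:
        raise InsufficientSpheresError(f"only {n} candidate centers (need >= 3)")
    if n > _MAX_CANDIDATES:
        raise CorrespondenceError(f"{n} candidates exceed the supported maximum of {_MAX_CANDIDATES}")
    D_geo = geometry.distance_matrix()
    D_cand = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)

    def _conflicts(a, b) -> bool:
        pa = dict(zip(a[2], a[3]))  # geometry index -> candidate index
        pb = dict(zip(b[2], b[3]))
        for gi in set(pa) & set(pb):
            if pa[gi] != pb[gi]:
                return True
        ca = {v: k for k, v in pa.items()}
        cb = {v: k for k, v in pb.items()}
        return any(ca[ci] != cb[ci] for ci in set(ca) & set(cb))

    chosen = None
    for k in range(min(n, m), 2, -1):
        scored = []
        for geo_sub in itertools.combinations(range(m), k):
            for cand_perm in itertools.permutations(range(n), k):
                diffs = [
                    abs(D_cand[cand_perm[a], cand_perm[b]] - D_geo[geo_sub[a], geo_sub[b]])
                    for a in range(k)
                    for b in range(a + 1, k)
                ]
                scored.append((float(np.mean(diffs)), float(np.max(diffs)), geo_sub, cand_perm))
        scored.sort(key=lambda s: s[0])
        best = scored[0]
        if best[1] > tol:
            continue  # no assignment of this size fits; retry with fewer spheres
        rival = next((s for s in scored[1:] if _conflicts(best, s)), None)
        if rival is not None and rival[0] - best[0] < ambiguity_margin:
            raise AmbiguousCorrespondenceError(
                f"two conflicting assignments within {ambiguity_margin} mm of each other "
                f"(best {best[0]:.3f}, rival {rival[0]:.3f} mm)"
            )
        chosen = best
        break

    if chosen is None:
        raise CorrespondenceError(
            f"no sphere assignment matches the marker distance pattern within {tol} mm"
        )
    mean_d, max_d, geo_sub, cand_perm = chosen
    order = np.argsort(geo_sub)
    geo_idx = np.asarray(geo_sub)[order]
    cand_idx = np.asarray(cand_perm)[order]
    return CorrespondenceResult(
        geometry_indices=geo_idx,
        candidate_indices=cand_idx,
        centers=centers[cand_idx],
        mean_mismatch_mm=mean_d,
        max_mismatch_mm=max_d,
    )


@dataclasses.dataclass(frozen=True)
class TrackedPose:
    """One estimated 6-DoF marker pose."""

    world_from_marker: RigidTransform
    timestamp: float
    n_spheres_used: int
    registration_rms_mm: float


def estimate_marker_pose(
    corr: CorrespondenceResult, geometry: MarkerGeometry, timestamp: float = 0.0
) -> TrackedPose:
    """Landmark-register reference sphere centers onto measured ones."""
    T, rms = rigid_register_landmarks(
        geometry.sphere_centers[corr.geometry_indices], corr.centers
    )
    return TrackedPose(T, timestamp, len(corr.geometry_indices), rms)


@dataclasses.dataclass(frozen=True)
class TrackerConfig:
    blob: BlobParams = dataclasses.field(default_factory=BlobParams)
    kalman: KalmanParams = dataclasses.field(default_factory=KalmanParams.static_setting)
    filter_enabled: bool = True
    match_tol_mm: float = 5.0
    ambiguity_margin_mm: float = 1.0


@dataclasses.dataclass
class FrameRecord:
    """Per-frame tracking diagnostics and intermediate measurements."""

    frame: int
    timestamp: float
    n_blobs: int
    pose: Optional[TrackedPose]
    raw_centers: dict  # geometry index -> (3,) corrected center
    filtered_centers: dict  # geometry index -> (3,) Kalman output (if enabled)
    observations: list
    error: str = ""


@dataclasses.dataclass
class TrackingResult:
    records: list
    geometry: MarkerGeometry
    config: TrackerConfig

    @property
    def poses(self) -> list:
        return [r.pose for r in self.records]

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([r.timestamp for r in self.records])

    def n_tracked(self) -> int:
        return sum(1 for r in self.records if r.pose is not None)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for r in self.records:
            row = {
                "frame": r.frame,
                "timestamp": r.timestamp,
                "n_blobs": r.n_blobs,
                "tracked": r.pose is not None,
                "error": r.error,
            }
            if r.pose is not None:
                q = r.pose.world_from_marker.to_quat_row(r.timestamp)
                for name, v in zip(("tx", "ty", "tz", "qw", "qx", "qy", "qz"), q[1:]):
                    row[name] = v
                row["n_spheres_used"] = r.pose.n_spheres_used
                row["registration_rms_mm"] = r.pose.registration_rms_mm
            for gi in range(self.geometry.n_spheres):
                for tag, store in (("raw", r.raw_centers), ("filt", r.filtered_centers)):
                    if gi in store:
                        row[f"s{gi}_{tag}_x"], row[f"s{gi}_{tag}_y"], row[f"s{gi}_{tag}_z"] = store[gi]
            rows.append(row)
        return pd.DataFrame(rows)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def track_sequence(
    frames: Iterable[DepthFrame],
    geometry: MarkerGeometry,
    lookup: Optional[LookupTable] = None,
    config: Optional[TrackerConfig] = None,
) -> TrackingResult:
    """Run the full tracking cycle over a frame sequence.

    ``frames`` may be any iterable of :class:`DepthFrame`; synthetic bundles
    carry their lookup table, so ``lookup`` can be omitted for them.  With
    ``config.filter_enabled`` each sphere's corrected world-frame center runs
    through its own constant-acceleration Kalman filter before registration.
    """
    if lookup is None:
        lookup = getattr(frames, "lookup", None)
    if lookup is None:
        raise InputError("no lookup table: pass lookup= or a bundle that carries one")
    config = config or TrackerConfig()
    r_s = geometry.sphere_radius
    tracks: dict[int, KalmanTrack] = {}
    records: list[FrameRecord] = []

    for fi, frame in enumerate(frames):
        t = frame.timestamp
        centers_px = detect_blobs(frame.ab, config.blob)
        obs = [measure_sphere(p, frame, lookup, r_s) for p in centers_px]
        valid_obs = [o for o in obs if o.valid]
        raw: dict[int, np.ndarray] = {}
        filtered: dict[int, np.ndarray] = {}
        pose = None
        err = ""

        corr = None
        if valid_obs:
            world_centers = np.array([o.world_center for o in valid_obs])
            try:
                corr = match_correspondences(
                    world_centers, geometry, config.match_tol_mm, config.ambiguity_margin_mm
                )
            except (InsufficientSpheresError, CorrespondenceError, AmbiguousCorrespondenceError) as e:
                err = f"{type(e).__name__}: {e}"
        else:
            err = "InsufficientSpheresError: no valid sphere observations"

        if corr is not None:
            for gi, ci in zip(corr.geometry_indices, corr.candidate_indices):
                raw[int(gi)] = corr.centers[list(corr.geometry_indices).index(gi)]
                valid_obs[ci].geometry_index = int(gi)

        if config.filter_enabled:
            for gi in range(geometry.n_spheres):
                track = tracks.get(gi, KalmanTrack(config.kalman))
                meas = raw.get(gi)
                if not track.initialized and meas is None:
                    continue
                track, pos = kalman_step(track, meas, t)
                tracks[gi] = track
                if meas is not None and pos is not None:
                    filtered[gi] = pos
            use = filtered
        else:
            use = raw

        if corr is not None and len(use) >= 3:
            gis = sorted(use.keys())
            pts = np.array([use[g] for g in gis])
            T, rms = rigid_register_landmarks(geometry.sphere_centers[gis], pts)
            pose = TrackedPose(T, t, len(gis), rms)

        records.append(
            FrameRecord(
                frame=fi,
                timestamp=t,
                n_blobs=len(centers_px),
                pose=pose,
                raw_centers=raw,
                filtered_centers=filtered,
                observations=obs,
                error=err,
            )
        )
    return TrackingResult(records=records, geometry=geometry, config=config)
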