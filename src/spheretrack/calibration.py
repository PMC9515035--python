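"""Ultrasound spatial calibration and temporal trajectory alignment.

Spatial calibration finds the rigid transform ``marker_from_image`` (M_T_US)
from a probe-mounted tracked marker to the origin of the B-mode ultrasound
image, using stylus-tip point pairs: the tip identified in the US image
(pixels) and simultaneously in an external reference tracker ("OT") frame.
Image points are scaled to mm, landmark-registered to the tracker points
(giving OT_T_US), and the loop is closed against the recorded static marker
pose:  M_T_US = (OT_T_M)^-1 . OT_T_US.

Image-plane convention: the US image origin is the top-left corner pixel
center, x along the image width, y along the B-mode depth direction, and the
image lies in the z = 0 plane of its own frame.

Temporal alignment estimates the clock offset between two trackers from a
shared sinusoidal motion segment by cross-correlating each trajectory's
projection onto its own principal motion axis (frame-invariant up to sign;
the alignment maximizes |correlation|).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .errors import AlignmentError, DegenerateGeometryError, InputError
from .geometry import RigidTransform, rigid_register_landmarks

__all__ = [
    "USImageGeometry",
    "StylusObservation",
    "CalibrationResult",
    "calibrate_image_to_marker",
    "place_image_in_world",
    "temporal_align",
]


@dataclasses.dataclass(frozen=True)
class USImageGeometry:
    """Size and scaling of the streamed B-mode image."""

    width_px: int = 512
    height_px: int = 512
    pixel_spacing_mm: tuple[float, float] = (0.078125, 0.078125)  # 40 mm / 512 px
    bits_per_pixel: int = 8

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise InputError("image dimensions must be positive")
        if min(self.pixel_spacing_mm) <= 0:
            raise InputError("pixel spacing must be positive")

    def pixel_to_mm(self, p: np.ndarray) -> np.ndarray:
        """Map (N, 2) pixel coordinates to (N, 3) mm points in the image frame."""
        p = np.atleast_2d(np.asarray(p, dtype=float))
        out = np.zeros((p.shape[0], 3))
        out[:, 0] = p[:, 0] * self.pixel_spacing_mm[0]
        out[:, 1] = p[:, 1] * self.pixel_spacing_mm[1]
        return out


@dataclasses.dataclass(frozen=True)
class StylusObservation:
    """One stylus-tip sighting: pixel location in the US image + tracker-frame point."""

    tip_image_px: np.ndarray  # (2,)
    tip_tracker_mm: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tip_image_px", np.asarray(self.tip_image_px, float).reshape(2))
        object.__setattr__(self, "tip_tracker_mm", np.asarray(self.tip_tracker_mm, float).reshape(3))


@dataclasses.dataclass(frozen=True)
class CalibrationResult:
    marker_from_image: RigidTransform  # M_T_US
    tracker_from_image: RigidTransform  # OT_T_US
    fiducial_rms_mm: float
    scale_residual_mm_per_px: float
    n_points: int


def calibrate_image_to_marker(
    observations: Sequence[StylusObservation],
    image_geom: USImageGeometry,
    tracker_from_marker: RigidTransform,
) -> CalibrationResult:
    """Solve the US spatial calibration from stylus-tip point pairs.

    Parameters
    ----------
    observations
        >= 3 non-collinear stylus sightings (pixel + tracker-frame mm point).
    image_geom
        Pixel spacing is taken as known from the US station; a residual scale
        check (per-axis point-spread mismatch, mm/px) is reported so a wrong
        spacing shows up as a large ``scale_residual_mm_per_px``.
    tracker_from_marker
        The static pose OT_T_M of the probe marker recorded during calibration.
    """
    if len(observations) < 3:
        raise InputError("calibration needs at least 3 stylus observations")
    px = np.array([o.tip_image_px for o in observations])
    for o in observations:
        if not (0 <= o.tip_image_px[0] < image_geom.width_px and 0 <= o.tip_image_px[1] < image_geom.height_px):
            raise InputError(f"stylus tip pixel {o.tip_image_px} outside US image")
    img_mm = image_geom.pixel_to_mm(px)
    trk_mm = np.array([o.tip_tracker_mm for o in observations])

    sv = np.linalg.svd(img_mm - img_mm.mean(0), compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("stylus tip points are collinear in the image plane")

    tracker_from_image, rms = rigid_register_landmarks(img_mm, trk_mm)
    marker_from_image = tracker_from_marker.inverse() @ tracker_from_image

    # scale sanity check: compare pairwise spans in both frames
    d_img = np.linalg.norm(img_mm[:, None] - img_mm[None, :], axis=-1)
    d_trk = np.linalg.norm(trk_mm[:, None] - trk_mm[None, :], axis=-1)
    iu = np.triu_indices(len(observations), k=1)
    span_px = np.linalg.norm(px[:, None] - px[None, :], axis=-1)[iu]
    scale_residual = float(np.mean(np.abs(d_trk[iu] - d_img[iu]) / np.maximum(span_px, 1e-9)))

    return CalibrationResult(
        marker_from_image=marker_from_image,
        tracker_from_image=tracker_from_image,
        fiducial_rms_mm=rms,
        scale_residual_mm_per_px=scale_residual,
        n_points=len(observations),
    )


def place_image_in_world(
    world_from_marker: RigidTransform,
    calib: CalibrationResult,
    image_geom: USImageGeometry,
) -> np.ndarray:
    """World-frame positions (mm) of the four US image corners.

    Corner order: origin, +x (width), +y (depth), +x+y.  The image is rigid,
    so opposite edges stay equal length under any pose.
    """
    w = image_geom.width_px * image_geom.pixel_spacing_mm[0]
    h = image_geom.height_px * image_geom.pixel_spacing_mm[1]
    corners_img = np.array([[0.0, 0.0, 0.0], [w, 0.0, 0.0], [0.0, h, 0.0], [w, h, 0.0]])
    T = world_from_marker @ calib.marker_from_image
    return T.apply(corners_img)


# -- temporal alignment ----------------------------------------------------


def _principal_signal(times: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Project positions onto their largest-variance axis, mean-centered.

    The axis sign is fixed by orienting its dominant coordinate positive, so
    two trackers whose frames are not mirrored/reversed produce sign-consistent
    signals.  (For a pure sinusoid seen from arbitrarily flipped frames a
    half-period ambiguity is inherent; this convention resolves it for the
    common case of roughly aligned frames.)
    """
    p = positions - positions.mean(axis=0)
    _, s, vt = np.linalg.svd(p, full_matrices=False)
    if s[0] <= 1e-9:
        raise AlignmentError("trajectory has no motion (flat signal)")
    v = vt[0]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return p @ v


def temporal_align(
    times_a: np.ndarray,
    positions_a: np.ndarray,
    times_b: np.ndarray,
    positions_b: np.ndarray,
) -> float:
    """Clock offset (s) between two trajectories of the same physical motion.

    Returns ``shift`` such that ``b(t) ~ a(t - shift)``: positive means B lags
    A.  Both trajectories are projected onto their own principal motion axis,
    resampled to the lower of the two rates, mean-centered, and the argmax of
    the cross-correlation (parabolically refined to sub-sample precision)
    gives the shift; ``temporal_align(a, b) == -temporal_align(b, a)`` within
    a sample.
    """
    ta = np.asarray(times_a, float)
    tb = np.asarray(times_b, float)
    pa = np.atleast_2d(np.asarray(positions_a, float))
    pb = np.atleast_2d(np.asarray(positions_b, float))
    if len(ta) < 8 or len(tb) < 8:
        raise AlignmentError("trajectories too short to align")

    rate_a = (len(ta) - 1) / (ta[-1] - ta[0])
    rate_b = (len(tb) - 1) / (tb[-1] - tb[0])
    dt = 1.0 / min(rate_a, rate_b)

    sa = _principal_signal(ta, pa)
    sb = _principal_signal(tb, pb)

    ga = np.arange(ta[0], ta[-1] + dt / 2, dt)
    gb = np.arange(tb[0], tb[-1] + dt / 2, dt)
    ua = np.interp(ga, ta, sa)
    ub = np.interp(gb, tb, sb)
    ua -= ua.mean()
    ub -= ub.mean()
    if np.std(ua) <= 1e-9 or np.std(ub) <= 1e-9:
        raise AlignmentError("flat signal after resampling")

    c = _signal.correlate(ub, ua, mode="full")
    k = int(np.argmax(c))
    # parabolic sub-sample refinement
    if 0 < k < len(c) - 1:
        y0, y1, y2 = c[k - 1 : k + 2]
        denom = y0 - 2 * y1 + y2
        frac = 0.0 if abs(denom) < 1e-12 else 0.5 * (y0 - y2) / denom
        frac = float(np.clip(frac, -0.5, 0.5))
    else:
        frac = 0.0
    lag = (k + frac) - (len(ua) - 1)
    return float(lag * dt + (gb[0] - ga[0]))
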