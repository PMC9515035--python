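"""Depth-camera model: lookup-table back-projection and world-frame chaining.

The sensor this emulates delivers, per frame, a 512x512 16-bit depth image and
a co-registered 512x512 16-bit active-brightness (AB) infrared image, together
with two extrinsic transforms: the pose of a reference (left-front) camera in
the world frame and the fixed offset from that reference camera to the depth
camera.  Back-projection goes through a static per-pixel lookup table of unit
ray directions; a pixel's 3-D point is ``depth * ray``.

Depth semantics: the stored depth value is the *range along the unit ray*
(not the z-coordinate), so ``||backproject(p, d)|| == d`` for every pixel.
A depth value of 0 encodes an invalid pixel.

Pixel convention: 0-based indices, pixel centers at integer coordinates,
``p = (x, y)`` = (column, row).  Detected blob centers are continuous; ray
directions at non-integer positions are evaluated analytically from the
pinhole model when the table carries one, else by bilinear interpolation of
the table followed by renormalization.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .errors import InputError, InvalidDepthError
from .geometry import RigidTransform

__all__ = [
    "LookupTable",
    "DepthFrame",
    "CameraRig",
    "build_lookup_table",
    "backproject_pixel",
    "surface_point_to_world",
    "camera_center",
]

SENSOR_SHAPE = (512, 512)


@dataclasses.dataclass(frozen=True)
class LookupTable:
    """Per-pixel unit ray directions ``[u, v, w]`` of the depth camera.

    ``entries[row, col]`` is the unit vector along the ray through pixel
    ``(x=col, y=row)``.  ``focal_px`` / ``principal_point`` are retained when
    the table was built from a pinhole model, enabling exact evaluation at
    subpixel positions.
    """

    entries: np.ndarray
    focal_px: Optional[float] = None
    principal_point: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 3 or e.shape[2] != 3:
            raise InputError(f"lookup table must be (H, W, 3), got {e.shape}")
        object.__setattr__(self, "entries", e)
        if self.principal_point is not None:
            object.__setattr__(
                self, "principal_point", np.asarray(self.principal_point, dtype=float).reshape(2)
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape[:2]

    def direction(self, p) -> np.ndarray:
        """Unit ray direction at continuous pixel position ``p = (x, y)``.

        Uses the exact pinhole formula when the model parameters are present,
        otherwise bilinear interpolation of the table entries (renormalized).
        """
        p = np.asarray(p, dtype=float).reshape(2)
        h, w = self.shape
        if not (0 <= p[0] <= w - 1 and 0 <= p[1] <= h - 1):
            raise InputError(f"pixel {p} outside {w}x{h} image")
        if self.focal_px is not None and self.principal_point is not None:
            v = np.array(
                [
                    (p[0] - self.principal_point[0]) / self.focal_px,
                    (p[1] - self.principal_point[1]) / self.focal_px,
                    1.0,
                ]
            )
            return v / np.linalg.norm(v)
        x0, y0 = int(np.floor(p[0])), int(np.floor(p[1]))
        x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
        fx, fy = p[0] - x0, p[1] - y0
        v = (
            (1 - fx) * (1 - fy) * self.entries[y0, x0]
            + fx * (1 - fy) * self.entries[y0, x1]
            + (1 - fx) * fy * self.entries[y1, x0]
            + fx * fy * self.entries[y1, x1]
        )
        return v / np.linalg.norm(v)


def build_lookup_table(
    focal_px: float,
    principal_point,
    shape: tuple[int, int] = SENSOR_SHAPE,
) -> LookupTable:
    """Construct an ideal-pinhole lookup table.

    The entry at pixel ``(x, y)`` is the unit vector along the ray through the
    pixel center: ``normalize(((x - cx)/f, (y - cy)/f, 1))``.  The real device
    ships a calibrated table; the simulator builds this ideal one (an optional
    per-pixel perturbation for miscalibration studies is applied by the caller
    on ``entries`` directly).
    """
    if focal_px <= 0:
        raise InputError(f"focal length must be positive, got {focal_px}")
    pp = np.asarray(principal_point, dtype=float).reshape(2)
    h, w = shape
    if not (0 <= pp[0] <= w - 1 and 0 <= pp[1] <= h - 1):
        raise InputError(f"principal point {pp} outside {w}x{h} image")
    xs = (np.arange(w) - pp[0]) / focal_px
    ys = (np.arange(h) - pp[1]) / focal_px
    gx, gy = np.meshgrid(xs, ys)
    e = np.stack([gx, gy, np.ones_like(gx)], axis=-1)
    e /= np.linalg.norm(e, axis=-1, keepdims=True)
    return LookupTable(entries=e, focal_px=float(focal_px), principal_point=pp)


@dataclasses.dataclass
class DepthFrame:
    """One synchronized depth + active-brightness image pair with camera metadata.

    ``depth`` is in mm (0 = invalid pixel); in memory both images may be float
    (quantization to 16-bit happens on write).  ``world_from_left`` is the
    reference-camera pose in the world frame; ``left_from_depth`` the fixed
    extrinsic from reference camera to depth camera.
    """

    depth: np.ndarray
    ab: np.ndarray
    world_from_left: RigidTransform
    left_from_depth: RigidTransform
    timestamp: float

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        self.ab = np.asarray(self.ab)
        if self.depth.shape != self.ab.shape or self.depth.ndim != 2:
            raise InputError(
                f"depth {self.depth.shape} and AB {self.ab.shape} must be equal 2-D shapes"
            )
        if self.timestamp < 0:
            raise InputError("timestamp must be non-negative")

    @property
    def world_from_depth(self) -> RigidTransform:
        return self.world_from_left @ self.left_from_depth


@dataclasses.dataclass(frozen=True)
class CameraRig:
    """Static camera description used by the simulator and the tracker."""

    lookup: LookupTable
    world_from_left: RigidTransform
    left_from_depth: RigidTransform

    @property
    def world_from_depth(self) -> RigidTransform:
        return self.world_from_left @ self.left_from_depth

    @property
    def center_world(self) -> np.ndarray:
        """Depth-camera center in the world frame (mm)."""
        return self.world_from_depth.translation


def backproject_pixel(p, d_p: float, L: LookupTable) -> np.ndarray:
    """Back-project pixel ``p`` with range ``d_p`` (mm) into the depth-camera frame.

    Returns ``d_p * L(p)``.  Raises :class:`InvalidDepthError` for ``d_p == 0``
    (the sensor's invalid code) and :class:`InputError` for negative depth or
    out-of-bounds pixels.
    """
    if d_p == 0:
        raise InvalidDepthError(f"invalid (zero) depth at pixel {p}")
    if d_p < 0:
        raise InputError(f"negative depth {d_p}")
    return d_p * L.direction(p)


def surface_point_to_world(D_s: np.ndarray, frame: DepthFrame) -> np.ndarray:
    """Chain a depth-camera-frame point into the world frame.

    ``W_s = world_from_left o left_from_depth (D_s)``.
    """
    return frame.world_from_depth.apply(np.asarray(D_s, dtype=float))


def camera_center(frame: DepthFrame) -> np.ndarray:
    """Depth-camera center in the world frame (origin pushed through the chain)."""
    return frame.world_from_depth.apply(np.zeros(3))
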