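"""Frame-bundle disk I/O.

A frame bundle is a directory holding one 16-bit grayscale PNG pair per frame
plus JSON metadata::

    bundle.json               # camera model, depth unit, frame count, units
    frame_000000_depth.png    # uint16, depth in units of depth_unit_mm (0 = invalid)
    frame_000000_ab.png       # uint16 active-brightness image
    frame_000000.json         # timestamp, world_from_left, left_from_depth (4x4)
    ...

Writing quantizes: depth is rounded to multiples of ``depth_unit_mm``
(default 1 mm, i.e. integer millimetres) and AB to integer intensity levels.
Write-then-read is bit-exact for the stored images and lossless (<= 1e-12)
for the transforms.
"""

from __future__ import annotations

import json
import os
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

from .camera import CameraRig, DepthFrame, LookupTable, build_lookup_table
from .errors import BundleFormatError, InputError
from .geometry import RigidTransform

__all__ = ["write_frame_bundle", "read_frame_bundle"]

_DEPTH_FMT = "frame_{:06d}_depth.png"
_AB_FMT = "frame_{:06d}_ab.png"
_SIDECAR_FMT = "frame_{:06d}.json"


def _quantize(img: np.ndarray, scale: float, what: str, frame: int) -> np.ndarray:
    q = np.round(np.asarray(img, dtype=float) / scale)
    if q.min() < 0:
        raise InputError(f"negative {what} values in frame {frame}")
    if q.max() > 65535:
        raise InputError(
            f"{what} overflow in frame {frame}: max {q.max() * scale:.0f} exceeds "
            f"16-bit range ({65535 * scale:.0f})"
        )
    return q.astype(np.uint16)


def write_frame_bundle(
    frames: Sequence[DepthFrame],
    path,
    lookup: Optional[LookupTable] = None,
    depth_unit_mm: float = 1.0,
    extra_meta: Optional[dict] = None,
) -> None:
    """Write frames (and optionally the camera model) to a bundle directory."""
    os.makedirs(path, exist_ok=True)
    frames = list(frames)
    prev_ts = -np.inf
    for i, f in enumerate(frames):
        if f.timestamp <= prev_ts:
            raise InputError(f"non-monotone timestamp at frame {i}")
        prev_ts = f.timestamp
        iio.imwrite(os.path.join(path, _DEPTH_FMT.format(i)), _quantize(f.depth, depth_unit_mm, "depth", i))
        iio.imwrite(os.path.join(path, _AB_FMT.format(i)), _quantize(f.ab, 1.0, "AB intensity", i))
        sidecar = {
            "timestamp": f.timestamp,
            "world_from_left": f.world_from_left.matrix.tolist(),
            "left_from_depth": f.left_from_depth.matrix.tolist(),
        }
        with open(os.path.join(path, _SIDECAR_FMT.format(i)), "w") as fh:
            json.dump(sidecar, fh)
    meta = {
        "format": "spheretrack-frame-bundle-v1",
        "frame_count": len(frames),
        "units": "mm",
        "depth_unit_mm": depth_unit_mm,
    }
    if lookup is not None and lookup.focal_px is not None:
        meta["camera"] = {
            "model": "pinhole",
            "focal_px": lookup.focal_px,
            "principal_point": list(map(float, lookup.principal_point)),
            "shape": list(lookup.shape),
        }
    if extra_meta:
        meta.update(extra_meta)
    with open(os.path.join(path, "bundle.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def _load_sidecar(path, i: int) -> dict:
    sidecar_path = os.path.join(path, _SIDECAR_FMT.format(i))
    if not os.path.exists(sidecar_path):
        raise BundleFormatError(f"missing sidecar for frame {i}: {sidecar_path}")
    with open(sidecar_path) as fh:
        d = json.load(fh)
    for key in ("timestamp", "world_from_left", "left_from_depth"):
        if key not in d:
            raise BundleFormatError(f"sidecar of frame {i} is missing '{key}'")
    return d


def read_frame_bundle(path) -> tuple[list[DepthFrame], Optional[LookupTable], dict]:
    """Read a bundle directory; returns ``(frames, lookup_or_None, metadata)``.

    Depth images are rescaled back to float mm using the stored depth unit;
    AB images are returned as stored (uint16).
    """
    meta_path = os.path.join(path, "bundle.json")
    if not os.path.exists(meta_path):
        raise BundleFormatError(f"not a frame bundle (no bundle.json): {path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    n = int(meta.get("frame_count", 0))
    depth_unit = float(meta.get("depth_unit_mm", 1.0))
    lookup = None
    cam = meta.get("camera")
    if cam and cam.get("model") == "pinhole":
        lookup = build_lookup_table(cam["focal_px"], cam["principal_point"], tuple(cam["shape"]))

    frames: list[DepthFrame] = []
    prev_ts = -np.inf
    shape = None
    for i in range(n):
        depth_path = os.path.join(path, _DEPTH_FMT.format(i))
        ab_path = os.path.join(path, _AB_FMT.format(i))
        for p in (depth_path, ab_path):
            if not os.path.exists(p):
                raise BundleFormatError(f"missing image for frame {i}: {p}")
        depth = np.asarray(iio.imread(depth_path))
        ab = np.asarray(iio.imread(ab_path))
        if shape is None:
            shape = depth.shape
        if depth.shape != shape or ab.shape != shape:
            raise BundleFormatError(f"image shape mismatch at frame {i}")
        d = _load_sidecar(path, i)
        if d["timestamp"] <= prev_ts:
            raise BundleFormatError(f"non-monotone timestamp at frame {i}")
        prev_ts = d["timestamp"]
        frames.append(
            DepthFrame(
                depth=depth.astype(float) * depth_unit,
                ab=ab,
                world_from_left=RigidTransform.from_matrix(np.asarray(d["world_from_left"])),
                left_from_depth=RigidTransform.from_matrix(np.asarray(d["left_from_depth"])),
                timestamp=float(d["timestamp"]),
            )
        )
    return frames, lookup, meta


def read_camera_rig(path) -> CameraRig:
    """Convenience: rebuild the static camera rig of a bundle from frame 0."""
    frames, lookup, _ = read_frame_bundle(path)
    if not frames or lookup is None:
        raise BundleFormatError("bundle has no frames or no pinhole camera model")
    f0 = frames[0]
    return CameraRig(lookup=lookup, world_from_left=f0.world_from_left, left_from_depth=f0.left_from_depth)
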