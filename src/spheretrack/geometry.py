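"""Rigid-transform algebra, landmark registration, Euler angles, pivot calibration.

Conventions
-----------
* Column-vector homogeneous convention: a chain ``A @ B`` applies ``B`` first,
  then ``A``; points multiply on the right.
* All lengths are millimetres; angles are degrees at the API surface.
* Euler angles use the intrinsic Z-Y-X (yaw-pitch-roll) order, a common
  robotics / image-guided-therapy convention.  ``EulerTriple.ry`` is the pitch;
  at pitch = +/-90 deg the decomposition is degenerate and the result is
  flagged via ``gimbal_lock`` (the yaw component absorbs the ambiguity).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, IllConditionedError, InputError

__all__ = [
    "RigidTransform",
    "EulerTriple",
    "LandmarkSet",
    "apply_transform",
    "rigid_register_landmarks",
    "rotation_to_euler",
    "euler_to_rotation",
    "pivot_calibrate",
    "PivotResult",
    "transforms_to_csv",
    "transforms_from_csv",
]

_ORTHO_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion: 3x3 rotation + 3-vector translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InputError(f"rotation must be 3x3, got {R.shape}")
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise InputError(f"rotation is not orthonormal (|R'R - I| = {err:.2e})")
        if np.linalg.det(R) < 0:
            raise InputError("rotation has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise InputError(f"homogeneous matrix must be 4x4, got {m.shape}")
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def from_rotvec(cls, rotvec_deg: Sequence[float], translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        R = Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True).as_matrix()
        return cls(R, np.asarray(translation, float))

    @classmethod
    def random(cls, rng: np.random.Generator, translation_scale: float = 100.0) -> "RigidTransform":
        """A uniformly random rotation with Gaussian translation (testing aid)."""
        R = Rotation.random(random_state=rng).as_matrix()
        return cls(R, rng.normal(0.0, translation_scale, 3))

    # -- algebra ----------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self`` after ``other``: (self o other)(p) = self(other(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to a 3-vector or an (N, 3) array of points (mm)."""
        p = np.asarray(points, dtype=float)
        if p.ndim == 1:
            return self.rotation @ p + self.translation
        return p @ self.rotation.T + self.translation

    # -- serialization ----------------------------------------------------
    def to_json_dict(self) -> dict:
        return {"matrix": self.matrix.tolist()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "RigidTransform":
        return cls.from_matrix(np.asarray(d["matrix"], dtype=float))

    def to_quat_row(self, timestamp: float) -> list[float]:
        """CSV row: timestamp, tx, ty, tz, qw, qx, qy, qz."""
        q = Rotation.from_matrix(self.rotation).as_quat()  # x, y, z, w
        t = self.translation
        return [timestamp, t[0], t[1], t[2], q[3], q[0], q[1], q[2]]

    @classmethod
    def from_quat_row(cls, row: Sequence[float]) -> tuple[float, "RigidTransform"]:
        ts, tx, ty, tz, qw, qx, qy, qz = (float(v) for v in row[:8])
        R = Rotation.from_quat([qx, qy, qz, qw]).as_matrix()
        return ts, cls(R, np.array([tx, ty, tz]))

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() < tol
            and np.abs(self.translation - other.translation).max() < tol
        )


@dataclasses.dataclass(frozen=True)
class EulerTriple:
    """Intrinsic Z-Y-X Euler angles in degrees (rx = roll, ry = pitch, rz = yaw)."""

    rx: float
    ry: float
    rz: float
    gimbal_lock: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz])

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.as_array()))


@dataclasses.dataclass(frozen=True)
class LandmarkSet:
    """An ordered set of >= 3 labelled 3-D points (mm) in a named frame."""

    points: np.ndarray
    frame_label: str = ""

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.points, dtype=float))
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 3:
            raise InputError(f"landmark set needs an (N>=3, 3) array, got {p.shape}")
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return self.points.shape[0]


def apply_transform(T: RigidTransform, p: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return T.apply(p)


def _as_points(x) -> np.ndarray:
    if isinstance(x, LandmarkSet):
        return x.points
    return np.atleast_2d(np.asarray(x, dtype=float))


def rigid_register_landmarks(source, target) -> tuple[RigidTransform, float]:
    """Least-squares rigid registration of corresponding point sets.

    Finds the proper rigid transform ``T`` minimizing
    ``sum_i || T(source_i) - target_i ||^2`` by the SVD (Kabsch) closed form
    with the determinant reflection fix, and returns ``(T, rms_residual_mm)``.

    Raises
    ------
    InputError
        If the sets differ in size or have fewer than 3 points.
    DegenerateGeometryError
        If the source points are collinear (rotation not identifiable).
    """
    src = _as_points(source)
    tgt = _as_points(target)
    if src.shape != tgt.shape:
        raise InputError(f"point set size mismatch: {src.shape} vs {tgt.shape}")
    if src.shape[0] < 3:
        raise InputError("registration needs at least 3 point pairs")

    cs = src.mean(axis=0)
    ct = tgt.mean(axis=0)
    src0 = src - cs
    tgt0 = tgt - ct

    sv = np.linalg.svd(src0, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("source landmarks are (nearly) collinear")

    H = src0.T @ tgt0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ct - R @ cs
    T = RigidTransform(R, t)
    rms = float(np.sqrt(np.mean(np.sum((T.apply(src) - tgt) ** 2, axis=1))))
    return T, rms


def rotation_to_euler(rotation) -> EulerTriple:
    """Decompose a rotation into intrinsic Z-Y-X Euler angles (degrees).

    Accepts a :class:`RigidTransform` or a 3x3 matrix.  Near pitch = +/-90 deg
    the triple is flagged ``gimbal_lock`` (rz absorbs the free angle).
    """
    R = rotation.rotation if isinstance(rotation, RigidTransform) else np.asarray(rotation, float)
    rz, ry, rx = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
    lock = abs(abs(ry) - 90.0) < 1e-6
    return EulerTriple(float(rx), float(ry), float(rz), gimbal_lock=lock)


def euler_to_rotation(e) -> np.ndarray:
    """Inverse of :func:`rotation_to_euler`; accepts an EulerTriple or (rx, ry, rz)."""
    if isinstance(e, EulerTriple):
        rx, ry, rz = e.rx, e.ry, e.rz
    else:
        rx, ry, rz = e
    return Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True).as_matrix()


@dataclasses.dataclass(frozen=True)
class PivotResult:
    """Output of :func:`pivot_calibrate`."""

    tip_offset: np.ndarray  # stylus tip in the tool frame, mm
    pivot_point: np.ndarray  # fixed tip location in the world frame, mm
    rms: float  # mm


def pivot_calibrate(poses: Iterable[RigidTransform], cond_limit: float = 1e8) -> PivotResult:
    """Pivot calibration of a tracked stylus.

    Given tool poses ``T_i = (R_i, t_i)`` recorded while the stylus rotates
    about a physically fixed tip, solves the linear least-squares system

        R_i p_tool + t_i = p_world        for all i

    for the tip offset ``p_tool`` (tool frame) and the pivot ``p_world``.

    Raises
    ------
    InputError
        Fewer than 3 poses.
    IllConditionedError
        Insufficient rotation diversity (e.g. pure translations), detected by
        the condition number of the stacked system exceeding ``cond_limit``.
    """
    poses = list(poses)
    if len(poses) < 3:
        raise InputError("pivot calibration needs at least 3 poses")
    n = len(poses)
    A = np.zeros((3 * n, 6))
    b = np.zeros(3 * n)
    for i, T in enumerate(poses):
        A[3 * i : 3 * i + 3, :3] = T.rotation
        A[3 * i : 3 * i + 3, 3:] = -np.eye(3)
        b[3 * i : 3 * i + 3] = -T.translation
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > cond_limit:
        raise IllConditionedError(
            "pivot poses lack rotation diversity (condition number "
            f"{np.inf if sv[-1] <= 0 else sv[0] / sv[-1]:.1e})"
        )
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = A @ x - b
    rms = float(np.sqrt(np.mean(np.sum(resid.reshape(n, 3) ** 2, axis=1))))
    return PivotResult(tip_offset=x[:3], pivot_point=x[3:], rms=rms)


# -- trajectory CSV serialization -----------------------------------------


def transforms_to_csv(path, timestamps: Sequence[float], transforms: Sequence[RigidTransform]) -> None:
    """Write a trajectory as CSV rows ``timestamp,tx,ty,tz,qw,qx,qy,qz``."""
    if len(timestamps) != len(transforms):
        raise InputError("timestamps and transforms differ in length")
    with open(path, "w") as fh:
        fh.write("timestamp,tx,ty,tz,qw,qx,qy,qz\n")
        for ts, T in zip(timestamps, transforms):
            row = T.to_quat_row(float(ts))
            fh.write(",".join(f"{v:.12g}" for v in row) + "\n")


def transforms_from_csv(path) -> tuple[np.ndarray, list[RigidTransform]]:
    timestamps: list[float] = []
    transforms: list[RigidTransform] = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header[:4] != ["timestamp", "tx", "ty", "tz"]:
            raise InputError(f"unexpected trajectory CSV header: {header}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            ts, T = RigidTransform.from_quat_row([float(v) for v in line.split(",")])
            timestamps.append(ts)
            transforms.append(T)
    return np.asarray(timestamps), transforms


def transform_to_json(T: RigidTransform, path) -> None:
    with open(path, "w") as fh:
        json.dump(T.to_json_dict(), fh, indent=1)


def transform_from_json(path) -> RigidTransform:
    with open(path) as fh:
        return RigidTransform.from_json_dict(json.load(fh))
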