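"""Shared numeric helpers for the test suite."""

import numpy as np
from scipy.spatial.transform import Rotation


def rotation_error_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Geodesic angle between two rotation matrices, degrees.

    Quaternion-based: numerically stable near identity (unlike the arccos of
    the trace, whose resolution floor is ~1e-6 deg in float64).
    """
    return float(np.degrees(Rotation.from_matrix(R1.T @ R2).magnitude()))


def pose_errors(T_est, T_true) -> tuple[float, float]:
    """(translation mm, rotation deg) error between two RigidTransforms."""
    terr = float(np.linalg.norm(T_est.translation - T_true.translation))
    return terr, rotation_error_deg(T_est.rotation, T_true.rotation)


def random_rigid(rng, translation_scale=100.0):
    from spheretrack import RigidTransform

    return RigidTransform.random(rng, translation_scale)
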