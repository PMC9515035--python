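"""Per-sphere Kalman filtering with a 3-D constant-acceleration motion model.

Each tracked sphere center (mm, world frame) gets its own 9-state filter
(position, velocity, acceleration per axis).  Only the position is measured.
The process/measurement covariance scales ``sigma_q`` / ``sigma_r`` are the
small unitless values this method class quotes (static: 1e-4 / 1e-3, dynamic:
1e-4 / 1e-4); they are interpreted on a metre^2 scale and converted to the
internal millimetre units via ``unit_scale`` (1e6 mm^2/m^2).  This convention
is the package's own documented choice — see docs/methods.md.

Two process-noise shapes are available: ``"identity"`` (Q = q I9, the direct
reading of a scalar process-noise covariance) and ``"white_jerk"`` (continuous
white-noise jerk discretized over dt, the textbook constant-acceleration form).

A track that misses more than ``max_misses`` consecutive measurements, or
whose innovation exceeds ``innovation_gate_mm`` (the marker was physically
repositioned, as between poses of a static acquisition), resets to the next
measurement.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .errors import InputError

__all__ = ["KalmanParams", "KalmanTrack", "kalman_step"]


@dataclasses.dataclass(frozen=True)
class KalmanParams:
    sigma_q: float = 1e-4
    sigma_r: float = 1e-3
    unit_scale: float = 1e6  # mm^2 per m^2
    max_misses: int = 5
    innovation_gate_mm: float = 25.0
    p0: float = 1e3
    q_model: str = "identity"  # or "white_jerk"

    def __post_init__(self) -> None:
        if self.sigma_q <= 0 or self.sigma_r <= 0:
            raise InputError("sigma_q and sigma_r must be positive")
        if self.q_model not in ("identity", "white_jerk"):
            raise InputError(f"unknown q_model {self.q_model!r}")

    @classmethod
    def static_setting(cls, **kw) -> "KalmanParams":
        return cls(sigma_q=1e-4, sigma_r=1e-3, **kw)

    @classmethod
    def dynamic_setting(cls, **kw) -> "KalmanParams":
        return cls(sigma_q=1e-4, sigma_r=1e-4, **kw)


@dataclasses.dataclass
class KalmanTrack:
    """State of one sphere's filter (immutably updated by :func:`kalman_step`)."""

    params: KalmanParams
    state: Optional[np.ndarray] = None  # (9,) pos, vel, acc
    covariance: Optional[np.ndarray] = None  # (9, 9)
    last_timestamp: Optional[float] = None
    miss_count: int = 0

    @property
    def initialized(self) -> bool:
        return self.state is not None

    @property
    def position(self) -> Optional[np.ndarray]:
        return None if self.state is None else self.state[:3]


_H = np.zeros((3, 9))
_H[:, :3] = np.eye(3)


def _transition(dt: float) -> np.ndarray:
    F = np.eye(9)
    F[:3, 3:6] = dt * np.eye(3)
    F[:3, 6:9] = 0.5 * dt * dt * np.eye(3)
    F[3:6, 6:9] = dt * np.eye(3)
    return F


def _process_noise(params: KalmanParams, dt: float) -> np.ndarray:
    q = params.sigma_q * params.unit_scale
    if params.q_model == "identity":
        return q * np.eye(9)
    # white-noise jerk: Q = q * integral(F G G' F') over dt, per axis
    d5, d4, d3, d2 = dt**5 / 20, dt**4 / 8, dt**3 / 6, dt**3 / 3
    block = np.array([[d5, d4, d3], [d4, d2, dt**2 / 2], [d3, dt**2 / 2, dt]])
    Q = np.zeros((9, 9))
    for a in range(3):
        idx = np.array([a, a + 3, a + 6])
        Q[np.ix_(idx, idx)] = q * block
    return Q


def _fresh(params: KalmanParams, m: np.ndarray, t: float) -> KalmanTrack:
    state = np.zeros(9)
    state[:3] = m
    return KalmanTrack(params, state, params.p0 * np.eye(9), t, 0)


def kalman_step(
    track: KalmanTrack,
    measurement: Optional[np.ndarray],
    timestamp: float,
) -> tuple[KalmanTrack, Optional[np.ndarray]]:
    """Advance one filter cycle; returns ``(new_track, filtered_position)``.

    ``measurement`` is the measured sphere center (mm, world frame) or None
    for a missed detection (predict-only; ``miss_count`` increments, and after
    ``max_misses`` consecutive misses the track re-initializes on the next
    measurement).  Raises :class:`InputError` on a non-increasing timestamp.
    """
    p = track.params
    if measurement is not None:
        measurement = np.asarray(measurement, float).reshape(3)

    if not track.initialized:
        if measurement is None:
            return track, None
        t = _fresh(p, measurement, timestamp)
        return t, t.position.copy()

    if timestamp <= track.last_timestamp:
        raise InputError(
            f"non-increasing timestamp {timestamp} (last {track.last_timestamp})"
        )
    dt = timestamp - track.last_timestamp

    F = _transition(dt)
    x = F @ track.state
    P = F @ track.covariance @ F.T + _process_noise(p, dt)

    if measurement is None:
        misses = track.miss_count + 1
        new = KalmanTrack(p, x, P, timestamp, misses)
        if misses > p.max_misses:
            new = KalmanTrack(p, None, None, timestamp, misses)  # stale: await re-init
        return new, (None if new.state is None else new.state[:3].copy())

    innovation = measurement - x[:3]
    if float(np.linalg.norm(innovation)) > p.innovation_gate_mm:
        t = _fresh(p, measurement, timestamp)
        return t, t.position.copy()

    R = p.sigma_r * p.unit_scale * np.eye(3)
    S = P[:3, :3] + R
    K = np.linalg.solve(S.T, (_H @ P)).T  # P H' S^-1
    x = x + K @ innovation
    IKH = np.eye(9) - K @ _H
    P = IKH @ P @ IKH.T + K @ R @ K.T  # Joseph form
    P = 0.5 * (P + P.T)
    new = KalmanTrack(p, x, P, timestamp, 0)
    return new, x[:3].copy()
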