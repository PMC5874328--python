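"""Hamilton quaternion helpers (scalar-first, sensor-to-global).

All rotations in this package use one fixed convention: unit quaternions
``(w, x, y, z)`` in the Hamilton convention, encoding the rotation from the
sensor (body) frame to the global frame. The global frame is Z-up with
gravity along -Z. Functions broadcast over leading axes, so a stream of N
quaternions is an ``(N, 4)`` array.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "qmul",
    "qconj",
    "qnormalize",
    "qrotate",
    "quat_about_axis",
    "quat_from_rotvec",
    "quat_to_matrix",
]


def qmul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product ``q1 * q2`` (apply q2 first, then q1)."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    """Quaternion conjugate (inverse for unit quaternions)."""
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qnormalize(q: np.ndarray) -> np.ndarray:
    """Rescale to unit norm; raises on (near-)zero quaternions."""
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("zero quaternion cannot be normalized")
    return q / norm


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate 3-vector(s) ``v`` from the sensor frame to the global frame."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qv = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    return qmul(qmul(q, qv), qconj(q))[..., 1:]


def quat_about_axis(angle_rad: np.ndarray, axis: str) -> np.ndarray:
    """Unit quaternion(s) for a rotation about a principal axis ('x'|'y'|'z')."""
    angle_rad = np.asarray(angle_rad, dtype=float)
    half = 0.5 * angle_rad
    c, s = np.cos(half), np.sin(half)
    zeros = np.zeros_like(c)
    i = "xyz".index(axis)
    comps = [zeros, zeros, zeros]
    comps[i] = s
    return np.stack([c] + comps, axis=-1)


def quat_from_rotvec(rotvec: np.ndarray) -> np.ndarray:
    """Quaternion from rotation vector (axis * angle, radians)."""
    rotvec = np.asarray(rotvec, dtype=float)
    angle = np.linalg.norm(rotvec, axis=-1, keepdims=True)
    small = angle < 1e-12
    axis = np.where(small, 0.0, rotvec / np.where(small, 1.0, angle))
    half = 0.5 * angle[..., 0]
    return np.concatenate(
        [np.cos(half)[..., None], np.sin(half)[..., None] * axis], axis=-1
    )


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix (sensor-to-global) for unit quaternion(s)."""
    w, x, y, z = np.moveaxis(np.asarray(q, dtype=float), -1, 0)
    row0 = np.stack(
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1
    )
    row1 = np.stack(
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1
    )
    row2 = np.stack(
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1
    )
    return np.stack([row0, row1, row2], axis=-2)
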