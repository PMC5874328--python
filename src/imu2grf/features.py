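"""Network input/target construction.

The orientation network (ANN_1) consumes the pelvis-relative orientations of
both shanks — eight quaternion components after sign-continuity — and
regresses the six sagittal joint angles. The force network (ANN_2) consumes
one of five feature combinations (pelvis vertical acceleration ``a_P``, all
three vertical accelerations ``a_{P+L}``, joint angles ``theta_joint``, or
the two combinations thereof) and regresses left/right vGRF in body weights.

Vertical accelerations are free accelerations in the global frame: specific
force rotated to the global frame by the sensor orientation, minus gravity
(g = 9.81 m/s^2), positive upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .quaternions import qconj, qmul, qnormalize, qrotate
from .preprocessing import SyncedTrial
from .synthetic import ANGLE_COLUMNS, G, JointAngleSeries

THETA_COLUMNS = tuple(f"theta_{c}" for c in ANGLE_COLUMNS)
ACCEL_COLUMNS = ("a_pelvis", "a_shank_left", "a_shank_right")


@dataclass(frozen=True)
class FeatureSet:
    """One of the five force-network feature combinations."""

    tag: str
    columns: Tuple[str, ...]


FEATURE_SETS: Dict[str, FeatureSet] = {
    "a_p": FeatureSet("a_p", ACCEL_COLUMNS[:1]),
    "a_pl": FeatureSet("a_pl", ACCEL_COLUMNS),
    "theta": FeatureSet("theta", THETA_COLUMNS),
    "a_p_theta": FeatureSet("a_p_theta", ACCEL_COLUMNS[:1] + THETA_COLUMNS),
    "a_pl_theta": FeatureSet("a_pl_theta", ACCEL_COLUMNS + THETA_COLUMNS),
}

ANN1_COLUMNS = tuple(
    f"q_rel_{side}_{c}" for side in ("left", "right") for c in "wxyz"
)


@dataclass
class FeatureMatrix:
    """Per-sample feature rows with named columns."""

    values: np.ndarray  # (n_samples, n_columns)
    column_names: Tuple[str, ...]
    sample_time: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("values shape does not match column_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")


def relative_orientation(q_pelvis: np.ndarray, q_shank: np.ndarray) -> np.ndarray:
    """Shank orientation expressed in the pelvis frame: conj(q_p) * q_s."""
    q_pelvis = np.asarray(q_pelvis, dtype=float)
    q_shank = np.asarray(q_shank, dtype=float)
    for q in (q_pelvis, q_shank):
        norms = np.linalg.norm(q, axis=-1)
        if np.any(norms < 1e-12):
            raise ValueError("zero quaternion")
        if np.abs(norms - 1.0).max() > 1e-6:
            raise ValueError("inputs must be unit quaternions within 1e-6")
    return qnormalize(qmul(qconj(q_pelvis), q_shank))


def enforce_sign_continuity(quat_series: np.ndarray) -> np.ndarray:
    """Resolve the q/-q double cover: consecutive dot products >= 0.

    The first quaternion is flipped to a non-negative scalar part; each
    subsequent one is flipped whenever its dot product with its predecessor
    is negative. Regression targets/inputs become continuous in time.
    """
    q = np.asarray(quat_series, dtype=float).copy()
    if q.ndim == 1:
        return q if q[0] >= 0 else -q
    if q[0, 0] < 0:
        q[0] = -q[0]
    dots = np.einsum("ij,ij->i", q[:-1], q[1:])
    q[1:] *= np.cumprod(np.where(dots < 0, -1.0, 1.0))[:, None]
    return q


def global_vertical_acceleration(
    q_sensor: np.ndarray, specific_force: np.ndarray
) -> np.ndarray:
    """Free vertical acceleration (m/s^2, positive up) in the global frame."""
    q_sensor = np.asarray(q_sensor, dtype=float)
    norms = np.linalg.norm(q_sensor, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("q_sensor must be unit norm")
    return qrotate(q_sensor, np.asarray(specific_force, dtype=float))[..., 2] - G


def build_ann1_io(
    trial: SyncedTrial, reference: str = "imu"
) -> Tuple[FeatureMatrix, np.ndarray]:
    """Orientation-network I/O: 8 relative-quaternion columns -> 6 angles."""
    ref = trial.ref_angles(reference)  # validates the tag
    cols = []
    for shank in (trial.quat_shank_left, trial.quat_shank_right):
        rel = relative_orientation(trial.quat_pelvis, shank)
        cols.append(enforce_sign_continuity(rel))
    x = np.concatenate(cols, axis=-1)
    y = ref.stack()
    return FeatureMatrix(x, ANN1_COLUMNS, trial.time), y


def build_ann2_io(
    angles: JointAngleSeries,
    trial: SyncedTrial,
    feature_set: FeatureSet | str = "a_pl_theta",
) -> Tuple[FeatureMatrix, np.ndarray]:
    """Force-network I/O per feature set; targets are (left, right) in BW.

    ``angles`` may be the reference kinematics (training) or the orientation
    network's estimates (inference); they must be sampled on the trial grid.
    """
    if isinstance(feature_set, str):
        try:
            feature_set = FEATURE_SETS[feature_set]
        except KeyError:
            raise ValueError(
                f"unknown feature set {feature_set!r}; expected one of "
                f"{sorted(FEATURE_SETS)}"
            ) from None
    if len(angles) != len(trial):
        raise ValueError("angles must be sampled at the trial rate")
    accel = {
        "a_pelvis": (trial.quat_pelvis, trial.accel_pelvis),
        "a_shank_left": (trial.quat_shank_left, trial.accel_shank_left),
        "a_shank_right": (trial.quat_shank_right, trial.accel_shank_right),
    }
    theta = dict(zip(THETA_COLUMNS, angles.stack().T))
    cols = []
    for name in feature_set.columns:
        if name in accel:
            q, f = accel[name]
            cols.append(global_vertical_acceleration(q, f))
        elif name in theta:
            cols.append(theta[name])
        else:  # pragma: no cover - FEATURE_SETS is closed
            raise ValueError(f"missing channel for feature {name!r}")
    x = np.stack(cols, axis=-1)
    bw = trial.subject.mass * G
    y = np.stack([trial.vgrf_left, trial.vgrf_right], axis=-1) / bw
    return FeatureMatrix(x, feature_set.columns, trial.time), y


@dataclass
class ScalerState:
    """Per-column affine map sending training min/max to [-1, +1]."""

    lo: np.ndarray
    hi: np.ndarray
    degenerate: np.ndarray  # constant training columns map to 0


def fit_scaler(x_train: np.ndarray) -> ScalerState:
    """Fit the per-column [-1, 1] min-max map on training data."""
    x_train = np.asarray(x_train, dtype=float)
    if x_train.ndim == 1:
        x_train = x_train[:, None]
    if len(x_train) < 2:
        raise ValueError("need at least 2 rows to fit a scaler")
    lo = x_train.min(axis=0)
    hi = x_train.max(axis=0)
    return ScalerState(lo=lo, hi=hi, degenerate=(hi == lo))


def apply_scaler(x: np.ndarray, state: ScalerState) -> np.ndarray:
    """Apply the stored affine map (values outside training range exceed +-1)."""
    x = np.asarray(x, dtype=float)
    span = np.where(state.degenerate, 1.0, state.hi - state.lo)
    scaled = 2.0 * (x - state.lo) / span - 1.0
    return np.where(state.degenerate, 0.0, scaled)


def invert_scaler(x_scaled: np.ndarray, state: ScalerState) -> np.ndarray:
    """Inverse of :func:`apply_scaler`; degenerate columns return their value."""
    x_scaled = np.asarray(x_scaled, dtype=float)
    span = np.where(state.degenerate, 1.0, state.hi - state.lo)
    raw = (x_scaled + 1.0) * span / 2.0 + state.lo
    return np.where(state.degenerate, state.lo, raw)
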