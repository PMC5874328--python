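"""Trial conditioning: cropping, force filtering, 120 Hz sync, segmentation.

The working representation downstream of this module is the
:class:`SyncedTrial`: all sensor and force streams on one 120 Hz time grid,
forces low-pass filtered (20 Hz, zero-phase 6th-order Butterworth) and
clipped non-negative, quaternions sign-continuous and re-normalised.
Stance phases are maximal runs of filtered vGRF >= 20 N, debounced with a
50 ms minimum phase duration; strides run from one ipsilateral contact to
the next.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.signal import butter, filtfilt

from .quaternions import qnormalize
from .synthetic import ANGLE_COLUMNS, JointAngleSeries, RawTrial, SubjectProfile

DEFAULT_RATE = 120.0
STANCE_THRESHOLD_N = 20.0
MIN_PHASE_S = 0.05


@dataclass(frozen=True)
class StanceSegment:
    """Half-open sample interval [start, end) of one foot contact."""

    side: str  # 'left' | 'right'
    start: int
    end: int
    t_contact: float  # s, time of the start sample

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.end <= self.start:
            raise ValueError("stance segment must satisfy end > start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Stride:
    """Ipsilateral contact to next ipsilateral contact, half-open."""

    side: str
    start: int
    end: int
    stance: StanceSegment


@dataclass
class SyncedTrial:
    """All streams aligned on one 120 Hz grid, ready for learning."""

    subject: SubjectProfile
    speed: float
    rate: float
    time: np.ndarray
    quat_pelvis: np.ndarray
    quat_shank_left: np.ndarray
    quat_shank_right: np.ndarray
    accel_pelvis: np.ndarray
    accel_shank_left: np.ndarray
    accel_shank_right: np.ndarray
    vgrf_left: np.ndarray
    vgrf_right: np.ndarray
    ref_angles_imu: JointAngleSeries
    ref_angles_optical: JointAngleSeries

    def __post_init__(self):
        n = len(self.time)
        streams = [
            self.quat_pelvis,
            self.quat_shank_left,
            self.quat_shank_right,
            self.accel_pelvis,
            self.accel_shank_left,
            self.accel_shank_right,
            self.vgrf_left,
            self.vgrf_right,
            self.ref_angles_imu.time,
            self.ref_angles_optical.time,
        ]
        if any(len(s) != n for s in streams):
            raise ValueError("all SyncedTrial streams must share one length")
        if min(self.vgrf_left.min(), self.vgrf_right.min()) < 0:
            raise ValueError("vGRF must be non-negative after clipping")

    def ref_angles(self, reference: str) -> JointAngleSeries:
        if reference == "imu":
            return self.ref_angles_imu
        if reference == "optical":
            return self.ref_angles_optical
        raise ValueError(f"unknown reference {reference!r}; expected 'imu'|'optical'")

    def vgrf(self, side: str) -> np.ndarray:
        if side not in ("left", "right"):
            raise ValueError(f"unknown side {side!r}")
        return self.vgrf_left if side == "left" else self.vgrf_right

    def __len__(self) -> int:
        return len(self.time)


def crop_steady_state(
    trial: RawTrial, trim_head: float, trim_tail: float
) -> RawTrial:
    """Drop treadmill spin-up/down: trim seconds from both ends of all streams."""
    residual = trial.duration - trim_head - trim_tail
    if residual < 5.0:
        raise ValueError(
            f"over-trimming: {residual:.2f} s would remain, need at least 5 s"
        )

    def cut(arr, rate):
        i0 = int(round(trim_head * rate))
        i1 = len(arr) - int(round(trim_tail * rate))
        return arr[i0:i1]

    def cut_angles(a: JointAngleSeries, rate):
        data = {c: cut(getattr(a, c), rate) for c in ANGLE_COLUMNS}
        t = cut(a.time, rate)
        return JointAngleSeries(time=t - t[0], **data)

    fr, ir = trial.force_rate, trial.imu_rate
    return dataclasses.replace(
        trial,
        force_left=cut(trial.force_left, fr),
        force_right=cut(trial.force_right, fr),
        quat_pelvis=cut(trial.quat_pelvis, ir),
        quat_shank_left=cut(trial.quat_shank_left, ir),
        quat_shank_right=cut(trial.quat_shank_right, ir),
        accel_pelvis=cut(trial.accel_pelvis, ir),
        accel_shank_left=cut(trial.accel_shank_left, ir),
        accel_shank_right=cut(trial.accel_shank_right, ir),
        ref_angles_imu=cut_angles(trial.ref_angles_imu, ir),
        ref_angles_optical=cut_angles(trial.ref_angles_optical, ir),
    )


def filter_vgrf(force: np.ndarray, fs: float, cutoff: float = 20.0) -> np.ndarray:
    """Zero-phase 6th-order Butterworth low-pass (effective 12th-order gain).

    Applied forward and backward (``filtfilt``) with reflective edge padding,
    so DC gain is exactly 1 and the amplitude at the cutoff is 0.5.
    """
    if fs <= 2.0 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff frequency")
    b, a = butter(6, cutoff, fs=fs)
    padlen = 3 * max(len(a), len(b))
    if len(force) <= padlen:
        raise ValueError(f"sequence too short to filter (need > {padlen} samples)")
    return filtfilt(b, a, np.asarray(force, dtype=float), padlen=padlen)


def _sign_continuous(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float).copy()
    if q[0, 0] < 0:
        q[0] = -q[0]
    dots = np.einsum("ij,ij->i", q[:-1], q[1:])
    flips = np.cumprod(np.where(dots < 0, -1.0, 1.0))
    q[1:] *= flips[:, None]
    return q


def _resample_stream(arr: np.ndarray, src_rate: float, t_new: np.ndarray) -> np.ndarray:
    ratio = src_rate / DEFAULT_RATE
    if abs(ratio - round(ratio)) < 1e-9:
        step = int(round(ratio))
        n = len(t_new)
        return np.asarray(arr, dtype=float)[: n * step : step]
    t_src = np.arange(len(arr)) / src_rate
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 1:
        return np.interp(t_new, t_src, arr)
    return np.stack(
        [np.interp(t_new, t_src, arr[:, i]) for i in range(arr.shape[1])], axis=-1
    )


def resample_trial(trial: RawTrial, target_rate: float = DEFAULT_RATE) -> SyncedTrial:
    """Synchronise all streams on a common 120 Hz grid.

    Integer-ratio streams (240 Hz IMU) are decimated by sample-picking;
    non-integer ratios (1000 Hz force, already band-limited to 20 Hz) are
    linearly interpolated onto the grid. Quaternions are made sign-continuous
    before decimation and re-normalised after.
    """
    if target_rate > min(trial.imu_rate, trial.force_rate):
        raise ValueError("target_rate exceeds a source stream rate")
    if target_rate != DEFAULT_RATE:
        raise NotImplementedError("the pipeline is defined at 120 Hz")
    dur = min(
        (len(trial.quat_pelvis) - 1) / trial.imu_rate,
        (len(trial.force_left) - 1) / trial.force_rate,
    )
    n = int(np.floor(dur * target_rate)) + 1
    t_new = np.arange(n) / target_rate

    def quat(arr):
        out = _resample_stream(_sign_continuous(arr), trial.imu_rate, t_new)
        return qnormalize(out)

    def imu(arr):
        return _resample_stream(arr, trial.imu_rate, t_new)

    def force(arr):
        return np.clip(_resample_stream(arr, trial.force_rate, t_new), 0.0, None)

    def angles(a: JointAngleSeries):
        data = {c: imu(getattr(a, c)) for c in ANGLE_COLUMNS}
        return JointAngleSeries(time=t_new.copy(), **data)

    return SyncedTrial(
        subject=trial.subject,
        speed=trial.speed,
        rate=target_rate,
        time=t_new,
        quat_pelvis=quat(trial.quat_pelvis),
        quat_shank_left=quat(trial.quat_shank_left),
        quat_shank_right=quat(trial.quat_shank_right),
        accel_pelvis=imu(trial.accel_pelvis),
        accel_shank_left=imu(trial.accel_shank_left),
        accel_shank_right=imu(trial.accel_shank_right),
        vgrf_left=force(trial.force_left),
        vgrf_right=force(trial.force_right),
        ref_angles_imu=angles(trial.ref_angles_imu),
        ref_angles_optical=angles(trial.ref_angles_optical),
    )


def preprocess_trial(
    trial: RawTrial, trim_head: float = 5.0, trim_tail: float = 5.0
) -> SyncedTrial:
    """Full conditioning pipeline: crop, filter forces, resample to 120 Hz."""
    cropped = crop_steady_state(trial, trim_head, trim_tail)
    cropped = dataclasses.replace(
        cropped,
        force_left=np.clip(filter_vgrf(cropped.force_left, cropped.force_rate), 0, None),
        force_right=np.clip(
            filter_vgrf(cropped.force_right, cropped.force_rate), 0, None
        ),
    )
    return resample_trial(cropped)


def segment_stances(
    vgrf: np.ndarray,
    fs: float,
    threshold: float = STANCE_THRESHOLD_N,
    min_phase: float = MIN_PHASE_S,
    side: str = "left",
) -> List[StanceSegment]:
    """Maximal runs of vGRF >= threshold, debounced, boundary contacts dropped.

    Runs shorter than ``min_phase`` are dropped and sub-``min_phase`` gaps
    between runs are merged (filter ripple near the threshold would otherwise
    double-trigger). Contacts touching either end of the sequence are
    discarded as incomplete.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    vgrf = np.asarray(vgrf, dtype=float)
    above = vgrf >= threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(vgrf))
    min_samples = int(np.ceil(min_phase * fs))
    # merge short gaps
    merged: List[Tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_samples:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    out = []
    for s, e in merged:
        if s == 0 or e == len(vgrf):  # incomplete boundary contact
            continue
        if e - s < max(min_samples, 1):
            continue
        out.append(StanceSegment(side=side, start=s, end=e, t_contact=s / fs))
    return out


def segment_strides(
    stances_left: List[StanceSegment], stances_right: List[StanceSegment]
) -> List[Stride]:
    """One stride per consecutive ipsilateral stance pair, time-ordered."""
    strides = []
    for stances in (stances_left, stances_right):
        for a, b in zip(stances[:-1], stances[1:]):
            strides.append(Stride(side=a.side, start=a.start, end=b.start, stance=a))
    return sorted(strides, key=lambda s: s.start)


def normalize_phase(
    series: np.ndarray, segment: Tuple[int, int], n_points: int = 101
) -> np.ndarray:
    """Resample ``series[start:end]`` onto ``n_points`` equal phase points.

    Linear interpolation over [start, end-1] with both endpoints preserved.
    """
    start, end = (segment.start, segment.end) if hasattr(segment, "start") else segment
    if end - start < 2:
        raise ValueError("degenerate segment: need end - start >= 2")
    series = np.asarray(series, dtype=float)
    x = np.linspace(start, end - 1, n_points)
    return np.interp(x, np.arange(len(series)), series)
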