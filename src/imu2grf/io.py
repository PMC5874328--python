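"""Plain-text interchange: trial CSVs, subject JSON, segmentation CSV.

A trial is exported as three UTF-8 CSV files with mandatory headers and '.'
decimal separators:

- ``<stem>_imu.csv``: time_s, then per sensor (pelvis/shankL/shankR)
  qw,qx,qy,qz,ax,ay,az
- ``<stem>_force.csv``: time_s, vgrf_left_N, vgrf_right_N
- ``<stem>_refangles.csv``: time_s, 6 angle columns for each reference
  variant (imu_*, optical_*)

Subject metadata round-trips through JSON with keys exactly matching
``SubjectProfile`` fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .preprocessing import StanceSegment
from .synthetic import (
    ANGLE_COLUMNS,
    JointAngleSeries,
    NoiseScales,
    RawTrial,
    SubjectProfile,
)

_SENSORS = (("pelvis", "pelvis"), ("shankL", "shank_left"), ("shankR", "shank_right"))


def write_trial_csv(trial: RawTrial, outdir, stem: str) -> List[Path]:
    """Write the three per-trial CSV files; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_imu = len(trial.quat_pelvis)
    t_imu = np.arange(n_imu) / trial.imu_rate

    imu_cols = {"time_s": t_imu}
    for prefix, attr in _SENSORS:
        q = getattr(trial, f"quat_{attr}")
        a = getattr(trial, f"accel_{attr}")
        for i, c in enumerate("wxyz"):
            imu_cols[f"{prefix}_q{c}"] = q[:, i]
        for i, c in enumerate("xyz"):
            imu_cols[f"{prefix}_a{c}"] = a[:, i]

    t_force = np.arange(len(trial.force_left)) / trial.force_rate
    force_cols = {
        "time_s": t_force,
        "vgrf_left_N": trial.force_left,
        "vgrf_right_N": trial.force_right,
    }

    ang_cols = {"time_s": t_imu}
    for variant, series in (
        ("imu", trial.ref_angles_imu),
        ("optical", trial.ref_angles_optical),
    ):
        for c in ANGLE_COLUMNS:
            ang_cols[f"{variant}_{c}"] = getattr(series, c)

    paths = []
    for suffix, cols in (
        ("imu", imu_cols),
        ("force", force_cols),
        ("refangles", ang_cols),
    ):
        path = outdir / f"{stem}_{suffix}.csv"
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
        paths.append(path)
    return paths


def read_trial_csv(
    directory, stem: str, subject: SubjectProfile, speed: float
) -> RawTrial:
    """Reassemble a RawTrial from the three CSV files."""
    directory = Path(directory)
    imu = pd.read_csv(directory / f"{stem}_imu.csv")
    force = pd.read_csv(directory / f"{stem}_force.csv")
    ang = pd.read_csv(directory / f"{stem}_refangles.csv")

    imu_rate = 1.0 / float(np.median(np.diff(imu["time_s"])))
    force_rate = 1.0 / float(np.median(np.diff(force["time_s"])))

    kwargs = {}
    for prefix, attr in _SENSORS:
        kwargs[f"quat_{attr}"] = imu[[f"{prefix}_q{c}" for c in "wxyz"]].to_numpy()
        kwargs[f"accel_{attr}"] = imu[[f"{prefix}_a{c}" for c in "xyz"]].to_numpy()

    t = imu["time_s"].to_numpy()
    refs = {}
    for variant in ("imu", "optical"):
        refs[variant] = JointAngleSeries(
            time=t.copy(),
            **{c: ang[f"{variant}_{c}"].to_numpy() for c in ANGLE_COLUMNS},
        )
    return RawTrial(
        subject=subject,
        speed=speed,
        force_left=force["vgrf_left_N"].to_numpy(),
        force_right=force["vgrf_right_N"].to_numpy(),
        ref_angles_imu=refs["imu"],
        ref_angles_optical=refs["optical"],
        force_rate=round(force_rate),
        imu_rate=round(imu_rate),
        **kwargs,
    )


def write_subject_json(subject: SubjectProfile, path) -> None:
    d = dataclasses.asdict(subject)
    d["noise_scales"] = dataclasses.asdict(subject.noise_scales)
    d["angle_template_coeffs"] = {
        j: [[float(c.real), float(c.imag)] for c in coeffs]
        for j, coeffs in subject.angle_template_coeffs.items()
    }
    Path(path).write_text(json.dumps(d, indent=1), encoding="utf-8")


def read_subject_json(path) -> SubjectProfile:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    d["noise_scales"] = NoiseScales(**d["noise_scales"])
    d["angle_template_coeffs"] = {
        j: np.array([complex(re, im) for re, im in coeffs])
        for j, coeffs in d["angle_template_coeffs"].items()
    }
    d["left_gains"] = {k: float(v) for k, v in d["left_gains"].items()}
    d["speed_gains"] = {k: float(v) for k, v in d["speed_gains"].items()}
    d["optical_offset"] = {k: tuple(v) for k, v in d["optical_offset"].items()}
    return SubjectProfile(**d)


def write_segments_csv(segments: List[StanceSegment], fs: float, path) -> None:
    """Export stance segments as (side, start_s, end_s) rows."""
    pd.DataFrame(
        {
            "side": [s.side for s in segments],
            "start_s": [s.start / fs for s in segments],
            "end_s": [s.end / fs for s in segments],
        }
    ).to_csv(path, index=False)
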