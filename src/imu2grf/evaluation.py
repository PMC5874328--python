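"""Study orchestration: the two evaluation scenarios and the ablations.

Scenario 1 (``single_subject_speed``): train on one subject's 10 and
14 km/h trials, evaluate on the held-out 12 km/h trial — the personalised
deployment mode. Scenario 2 (``leave_one_subject_out``): train on all trials
of the remaining subjects and evaluate on the held-out subject's 12 km/h
trial — the generic-model mode, expected to degrade with gait-style
diversity. The feature ablation repeats scenario 1 with each of the five
force-network feature sets (sharing the trained orientation network); the
speed-generalization study leaves each speed out in turn.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

log = logging.getLogger(__name__)

from . import metrics as mx
from .features import FEATURE_SETS
from .models import ConcatenatedEstimator, TrainConfig
from .preprocessing import (
    SyncedTrial,
    preprocess_trial,
    segment_stances,
    segment_strides,
)
from .synthetic import G, simulate_cohort

SIDES = ("left", "right")
DISCRETE_NAMES = ("max_knee_flexion_stance", "peak_vgrf", "loading_rate")


@dataclass
class Dataset:
    """Synchronized trials tagged by (subject, speed), plus provenance."""

    trials: List[SyncedTrial]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for t in self.trials:
            key = (t.subject.subject_id, float(t.speed))
            if key in seen:
                raise ValueError(f"duplicate (subject, speed) pair {key}")
            seen.add(key)

    @property
    def subjects(self) -> List[str]:
        return sorted({t.subject.subject_id for t in self.trials})

    def speeds_of(self, subject_id: str) -> List[float]:
        return sorted(
            float(t.speed) for t in self.trials if t.subject.subject_id == subject_id
        )

    def trial(self, subject_id: str, speed: float) -> SyncedTrial:
        for t in self.trials:
            if t.subject.subject_id == subject_id and float(t.speed) == float(speed):
                return t
        raise KeyError(
            f"no trial for {subject_id} at {speed} km/h; "
            f"available speeds: {self.speeds_of(subject_id)}"
        )

    def trials_of(self, subject_id: str, exclude_speed=None) -> List[SyncedTrial]:
        return [
            t
            for t in self.trials
            if t.subject.subject_id == subject_id
            and (exclude_speed is None or float(t.speed) != float(exclude_speed))
        ]


def make_dataset(
    n_subjects: int = 8,
    speeds: Sequence[float] = (10.0, 12.0, 14.0),
    duration: float = 60.0,
    seed: int = 0,
    trim: float = 5.0,
) -> Dataset:
    """Simulate and preprocess the full study design."""
    raw = simulate_cohort(n_subjects, tuple(speeds), duration, seed)
    trials = [preprocess_trial(t, trim, trim) for t in raw]
    return Dataset(
        trials=trials,
        provenance={
            "generator": "imu2grf.synthetic.simulate_cohort",
            "n_subjects": n_subjects,
            "speeds": list(map(float, speeds)),
            "duration_s": duration,
            "seed": int(seed),
            "trim_s": trim,
        },
    )


@dataclass
class SubjectEvaluation:
    """All outcome measures for one evaluated trial."""

    subject_id: str
    speed: float
    knee: Dict[str, mx.AgreementSummary]  # per side
    vgrf: Dict[str, mx.AgreementSummary]  # per side
    discrete_ref: Dict[str, mx.DiscreteOutcomes]  # per side
    discrete_est: Dict[str, mx.DiscreteOutcomes]
    p_values: Dict[str, float]  # per discrete outcome, sides pooled


@dataclass
class ScenarioResult:
    scenario: str  # 'single_subject_speed' | 'leave_one_subject_out'
    scheme: str
    feature_set: str
    per_subject: Dict[str, SubjectEvaluation]
    config: TrainConfig


def _evaluate_trial(
    estimator: ConcatenatedEstimator, trial: SyncedTrial, scheme: str
) -> SubjectEvaluation:
    """All metrics of one estimator on one held-out trial.

    Segmentation always uses the measured (reference) force; knee agreement
    is per stride, vGRF agreement per stance; the passive-peak time comes
    from the measured shank accelerometer and is shared by the estimate and
    the reference loading-rate computation.
    """
    from .features import global_vertical_acceleration

    est_angles, est_vgrf_bw = estimator.estimate(trial)
    ref_angles = trial.ref_angles(scheme)
    mass = trial.subject.mass
    fs = trial.rate

    stances = {
        side: segment_stances(trial.vgrf(side), fs, side=side) for side in SIDES
    }
    strides = {
        side: [s for s in segment_strides(stances["left"], stances["right"])
               if s.side == side]
        for side in SIDES
    }

    knee, vgrf = {}, {}
    discrete_ref, discrete_est = {}, {}
    for i, side in enumerate(SIDES):
        ref_knee = getattr(ref_angles, f"{side}_knee")
        est_knee = getattr(est_angles, f"{side}_knee")
        knee[side] = mx.summarize_agreement(
            [est_knee[s.start : s.end] for s in strides[side]],
            [ref_knee[s.start : s.end] for s in strides[side]],
        )
        ref_bw = trial.vgrf(side) / (mass * G)
        est_bw = est_vgrf_bw[:, i]
        vgrf[side] = mx.summarize_agreement(
            [est_bw[s.start : s.end] for s in stances[side]],
            [ref_bw[s.start : s.end] for s in stances[side]],
        )
        shank_accel = global_vertical_acceleration(
            getattr(trial, f"quat_shank_{side}"),
            getattr(trial, f"accel_shank_{side}"),
        )
        rows = {"ref": [], "est": []}
        for stance in stances[side]:
            t_pp = mx.passive_peak_time(shank_accel, stance, fs)
            if not 0.0 < t_pp or (0.8 - 0.2) * t_pp * fs < 0.5:
                continue  # impact event indistinguishable at this rate
            for tag, angle_series, force_n in (
                ("ref", ref_angles, trial.vgrf(side)),
                ("est", est_angles, est_bw * mass * G),
            ):
                rows[tag].append(
                    (
                        mx.max_knee_flexion_stance(angle_series, stance),
                        mx.peak_vgrf_bw(force_n, stance, mass),
                        t_pp,
                        mx.loading_rate(force_n, fs, stance, t_pp, mass),
                    )
                )
        for tag, target in (("ref", discrete_ref), ("est", discrete_est)):
            arr = np.array(rows[tag]) if rows[tag] else np.empty((0, 4))
            target[side] = mx.DiscreteOutcomes(
                max_knee_flexion_stance=arr[:, 0],
                peak_vgrf=arr[:, 1],
                t_passive_peak=arr[:, 2],
                loading_rate=arr[:, 3],
            )

    p_values = {}
    for name in DISCRETE_NAMES:
        ref_vals = np.concatenate([getattr(discrete_ref[s], name) for s in SIDES])
        est_vals = np.concatenate([getattr(discrete_est[s], name) for s in SIDES])
        if len(ref_vals) >= 2:
            _, p, _ = mx.paired_ttest(est_vals, ref_vals)
        else:
            p = float("nan")
        p_values[name] = p

    return SubjectEvaluation(
        subject_id=trial.subject.subject_id,
        speed=float(trial.speed),
        knee=knee,
        vgrf=vgrf,
        discrete_ref=discrete_ref,
        discrete_est=discrete_est,
        p_values=p_values,
    )


def scenario_single_subject(
    dataset: Dataset,
    subject_id: str,
    test_speed: float = 12.0,
    scheme: str = "imu",
    feature_set: str = "a_pl_theta",
    config: Optional[TrainConfig] = None,
    _reuse_ann1=None,
) -> ScenarioResult:
    """Train on a subject's other speeds, evaluate on ``test_speed``."""
    config = config or TrainConfig()
    train = dataset.trials_of(subject_id, exclude_speed=test_speed)
    if len(train) < 2:
        raise ValueError(
            f"subject {subject_id} needs >= 2 training speeds distinct from "
            f"{test_speed}; available: {dataset.speeds_of(subject_id)}"
        )
    test = dataset.trial(subject_id, test_speed)
    est = ConcatenatedEstimator(scheme=scheme, feature_set=feature_set, config=config)
    t0 = time.time()
    est.fit(train, ann1=_reuse_ann1)
    log.info(
        "single-subject %s: trained on %d trials in %.1f s (rows %s)",
        subject_id, len(train), time.time() - t0, est.metadata_["n_train_samples"],
    )
    ev = _evaluate_trial(est, test, scheme)
    return ScenarioResult(
        scenario="single_subject_speed",
        scheme=scheme,
        feature_set=feature_set,
        per_subject={subject_id: ev},
        config=config,
    )


def scenario_loso(
    dataset: Dataset,
    held_out_subject: str,
    scheme: str = "imu",
    feature_set: str = "a_pl_theta",
    config: Optional[TrainConfig] = None,
    test_speed: float = 12.0,
) -> ScenarioResult:
    """Train on all trials of the other subjects; evaluate held-out at 12 km/h."""
    config = config or TrainConfig()
    if len(dataset.subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    train = [
        t for t in dataset.trials if t.subject.subject_id != held_out_subject
    ]
    test = dataset.trial(held_out_subject, test_speed)
    est = ConcatenatedEstimator(scheme=scheme, feature_set=feature_set, config=config)
    t0 = time.time()
    est.fit(train)
    log.info(
        "LOSO holdout %s: trained on %d trials in %.1f s",
        held_out_subject, len(train), time.time() - t0,
    )
    ev = _evaluate_trial(est, test, scheme)
    return ScenarioResult(
        scenario="leave_one_subject_out",
        scheme=scheme,
        feature_set=feature_set,
        per_subject={held_out_subject: ev},
        config=config,
    )


def feature_ablation(
    dataset: Dataset,
    subject_id: str,
    config: Optional[TrainConfig] = None,
    scheme: str = "imu",
    test_speed: float = 12.0,
) -> Dict[str, ScenarioResult]:
    """Scenario 1 for each of the five feature sets, shared seeds and ANN_1."""
    from . import features as ft
    from .models import train_mlp

    config = config or TrainConfig()
    train = dataset.trials_of(subject_id, exclude_speed=test_speed)
    io1 = [ft.build_ann1_io(t, scheme) for t in train]
    x1 = np.concatenate([xm.values for xm, _ in io1])
    y1 = np.concatenate([y for _, y in io1])
    x1, y1 = ConcatenatedEstimator()._thin(x1, y1)  # same thinning as the scenarios
    shared_ann1 = train_mlp(x1, y1, config)
    return {
        tag: scenario_single_subject(
            dataset, subject_id, test_speed, scheme, tag, config,
            _reuse_ann1=shared_ann1,
        )
        for tag in FEATURE_SETS
    }


def speed_generalization(
    dataset: Dataset,
    subject_id: str,
    config: Optional[TrainConfig] = None,
    scheme: str = "imu",
    feature_set: str = "a_pl_theta",
) -> Dict[float, ScenarioResult]:
    """Leave-one-speed-out over all of the subject's speeds."""
    speeds = dataset.speeds_of(subject_id)
    if len(speeds) < 3:
        raise ValueError("speed generalization needs >= 3 speeds")
    return {
        speed: scenario_single_subject(
            dataset, subject_id, speed, scheme, feature_set, config
        )
        for speed in speeds
    }


# ---------------------------------------------------------------------------
# reporting

def _summary_dict(s: mx.AgreementSummary) -> dict:
    return {
        "rho": s.rho_mean,
        "rmse_mean": s.rmse_mean,
        "rmse_sd": s.rmse_sd,
        "n_segments": s.n_segments,
    }


def _discrete_dict(d: mx.DiscreteOutcomes) -> dict:
    out = {}
    for name in DISCRETE_NAMES + ("t_passive_peak",):
        vals = getattr(d, name)
        out[name] = {
            "mean": float(np.mean(vals)) if len(vals) else None,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
            "n": int(len(vals)),
        }
    return out


def result_to_dict(res: ScenarioResult) -> dict:
    config = dataclasses.asdict(res.config)
    config["hidden_sizes"] = list(config["hidden_sizes"])
    return {
        "scenario": res.scenario,
        "scheme": res.scheme,
        "feature_set": res.feature_set,
        "config": config,
        "subjects": {
            sid: {
                "speed": ev.speed,
                "knee": {s: _summary_dict(ev.knee[s]) for s in SIDES},
                "vgrf": {s: _summary_dict(ev.vgrf[s]) for s in SIDES},
                "discrete_ref": {s: _discrete_dict(ev.discrete_ref[s]) for s in SIDES},
                "discrete_est": {s: _discrete_dict(ev.discrete_est[s]) for s in SIDES},
                "p_values": ev.p_values,
            }
            for sid, ev in res.per_subject.items()
        },
    }


def render_report(results) -> Tuple[str, dict]:
    """Human-readable tables plus a lossless machine-readable summary.

    ``results`` is one ScenarioResult or a list; returns (text, summary)
    where ``summary`` survives a JSON round trip with identical numbers.
    """
    if isinstance(results, ScenarioResult):
        results = [results]
    if not results:
        raise ValueError("no results to report")
    blocks = []
    summary = {"results": [result_to_dict(r) for r in results]}
    for r in results:
        lines = [
            f"scenario={r.scenario} scheme={r.scheme} features={r.feature_set}",
            f"{'subject':<9}{'side':<7}{'knee rho':>9}{'knee RMSE (sd)':>17}"
            f"{'vGRF rho':>10}{'vGRF RMSE (sd)':>17}",
        ]
        for sid, ev in sorted(r.per_subject.items()):
            for side in SIDES:
                k, v = ev.knee[side], ev.vgrf[side]
                lines.append(
                    f"{sid:<9}{side:<7}{k.rho_mean:>9.3f}"
                    f"{k.rmse_mean:>10.2f} ({k.rmse_sd:.2f})"
                    f"{v.rho_mean:>10.3f}{v.rmse_mean:>11.3f} ({v.rmse_sd:.3f})"
                )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks), summary


def discrete_outcomes_table(res: ScenarioResult):
    """Per-stance discrete outcomes as a DataFrame (one row per stance),
    ready for CSV export."""
    import pandas as pd

    rows = []
    for sid, ev in sorted(res.per_subject.items()):
        for side in SIDES:
            ref, est = ev.discrete_ref[side], ev.discrete_est[side]
            for k in range(len(ref.peak_vgrf)):
                rows.append(
                    {
                        "subject": sid,
                        "side": side,
                        "stance": k,
                        "t_passive_peak_s": ref.t_passive_peak[k],
                        "max_knee_flexion_ref_deg": ref.max_knee_flexion_stance[k],
                        "max_knee_flexion_est_deg": est.max_knee_flexion_stance[k],
                        "peak_vgrf_ref_bw": ref.peak_vgrf[k],
                        "peak_vgrf_est_bw": est.peak_vgrf[k],
                        "loading_rate_ref_bw_s": ref.loading_rate[k],
                        "loading_rate_est_bw_s": est.loading_rate[k],
                    }
                )
    return pd.DataFrame(rows)


def row_fingerprints(x: np.ndarray) -> set:
    """Hashable per-row fingerprints, used to verify train/test disjointness."""
    x = np.ascontiguousarray(np.asarray(x, dtype=float))
    return {row.tobytes() for row in x}
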