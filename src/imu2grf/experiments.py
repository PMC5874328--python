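"""The canonical end-to-end validation experiment.

Simulates the full study design — 8 subjects (profile seeds 1..8, spanning
rearfoot/midfoot/forefoot strikers) x 3 speeds (10/12/14 km/h) x 60 s — and
runs both evaluation scenarios with the full-size networks (250/100 hidden
units, ``a_{P+L} & theta_joint`` features, inertial reference scheme):

* single-subject: train on 10 + 14 km/h, evaluate on 12 km/h, per subject;
* leave-one-subject-out: train on the 7 other subjects, evaluate the
  held-out subject's 12 km/h trial.

:func:`headline_numbers` condenses the result into the package's headline
accuracy figures (worst-case knee RMSE, Fisher-averaged correlations,
vGRF RMSE and peak-force agreement).
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from .evaluation import (
    ScenarioResult,
    make_dataset,
    scenario_loso,
    scenario_single_subject,
)
from .models import TrainConfig

SIDES = ("left", "right")


def run_headline_experiment(
    seed: int = 1,
    n_subjects: int = 8,
    speeds: Sequence[float] = (10.0, 12.0, 14.0),
    duration: float = 60.0,
    scheme: str = "imu",
    feature_set: str = "a_pl_theta",
) -> dict:
    """Run both scenarios over the whole cohort; returns all results.

    ``seed`` drives every random element: trial noise, network
    initialisation and the validation splits.
    """
    dataset = make_dataset(
        n_subjects=n_subjects, speeds=speeds, duration=duration, seed=seed
    )
    config = TrainConfig(seed=int(seed) % (2**31))
    single: Dict[str, ScenarioResult] = {}
    loso: Dict[str, ScenarioResult] = {}
    for sid in dataset.subjects:
        single[sid] = scenario_single_subject(
            dataset, sid, 12.0, scheme, feature_set, config
        )
    for sid in dataset.subjects:
        loso[sid] = scenario_loso(dataset, sid, scheme, feature_set, config)
    return {
        "dataset": dataset,
        "config": config,
        "single": single,
        "loso": loso,
    }


def _worse_side_rho(ev) -> float:
    return min(ev.knee[s].rho_mean for s in SIDES)


def headline_numbers(experiment: dict) -> dict:
    """Condense the experiment into the headline accuracy figures.

    Returns a dict with:

    - ``knee_rho_single``: Fisher-averaged per-stride knee correlation,
      worse side per subject, minimum after excluding the single worst
      subject (single-subject scenario)
    - ``knee_rmse_single``: per-stride knee RMSE averaged over strides and
      sides, worst case over subjects (degrees)
    - ``vgrf_rmse_single``: per-stance vGRF RMSE averaged over stances and
      sides, worst case over subjects (BW)
    - ``knee_rho_loso``: second-lowest worse-side knee correlation across
      the held-out subjects
    - ``peak_vgrf_err``: worst-case absolute difference between mean
      estimated and mean reference per-stance peak vGRF (BW)
    """
    single = experiment["single"]
    loso = experiment["loso"]
    subjects = sorted(single)
    n = len(subjects)

    single_rhos = []
    knee_rmses = []
    vgrf_rmses = []
    peak_errs = []
    for sid in subjects:
        ev = single[sid].per_subject[sid]
        single_rhos.append(_worse_side_rho(ev))
        knee_rmses.append(float(np.mean([ev.knee[s].rmse_mean for s in SIDES])))
        vgrf_rmses.append(float(np.mean([ev.vgrf[s].rmse_mean for s in SIDES])))
        ref_peaks = np.concatenate([ev.discrete_ref[s].peak_vgrf for s in SIDES])
        est_peaks = np.concatenate([ev.discrete_est[s].peak_vgrf for s in SIDES])
        peak_errs.append(abs(float(est_peaks.mean()) - float(ref_peaks.mean())))

    loso_rhos = sorted(_worse_side_rho(loso[sid].per_subject[sid]) for sid in subjects)

    return {
        "knee_rho_single": {"value": sorted(single_rhos)[1], "n": n},
        "knee_rmse_single": {"value": max(knee_rmses), "n": n},
        "vgrf_rmse_single": {"value": max(vgrf_rmses), "n": n},
        "knee_rho_loso": {"value": loso_rhos[1], "n": n},
        "peak_vgrf_err": {"value": max(peak_errs), "n": n},
    }
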