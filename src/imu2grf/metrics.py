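"""Outcome measures: continuous agreement and discrete gait landmarks.

Continuous agreement between estimate and reference is summarised per
stride (knee angles) or per stance (vGRF) as Pearson's rho — averaged
through the Fisher z-transform — and RMSE (mean and stride-to-stride SD).
Discrete outcomes per stance: maximum knee flexion, peak vGRF in body
weights, passive (impact) peak time from the shank accelerometer, and the
loading rate as the vGRF slope between 20% and 80% of the passive-peak
time. Method comparison uses paired two-sided t-tests (alpha 0.05) and
Bland-Altman bias / limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .preprocessing import StanceSegment
from .synthetic import G, JointAngleSeries

RHO_CLIP = 1.0 - 1e-12


@dataclass
class AgreementSummary:
    """Per-segment agreement statistics, aggregated."""

    rho_mean: float  # Fisher-averaged Pearson correlation
    rmse_mean: float
    rmse_sd: float
    n_segments: int


@dataclass
class DiscreteOutcomes:
    """One record per stance: stance-phase landmarks of a trial."""

    max_knee_flexion_stance: np.ndarray  # deg
    peak_vgrf: np.ndarray  # BW
    t_passive_peak: np.ndarray  # s from contact
    loading_rate: np.ndarray  # BW/s


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    differences: np.ndarray


def rmse(est: Sequence[float], ref: Sequence[float]) -> float:
    """Root mean squared error, unnormalised."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("est and ref must have equal length")
    if est.size < 1:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def pearson_rho(est: Sequence[float], ref: Sequence[float]) -> float:
    """Sample Pearson correlation; constant inputs are an error, not NaN."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("est and ref must have equal length")
    if est.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(est) == 0 or np.ptp(ref) == 0:
        raise ValueError("correlation undefined for a constant sequence")
    return float(stats.pearsonr(est, ref).statistic)


def fisher_mean_rho(rhos: Sequence[float]) -> float:
    """tanh(mean(atanh(rho))), rhos clipped to +-(1 - 1e-12)."""
    rhos = np.asarray(rhos, dtype=float)
    if rhos.size == 0:
        raise ValueError("empty correlation list")
    z = np.arctanh(np.clip(rhos, -RHO_CLIP, RHO_CLIP))
    return float(np.tanh(np.mean(z)))


def max_knee_flexion_stance(
    angles: JointAngleSeries, stance: StanceSegment
) -> float:
    """Maximum ipsilateral knee flexion (deg) over the stance interval."""
    knee = getattr(angles, f"{stance.side}_knee")
    if stance.end > len(knee):
        raise ValueError("stance extends beyond the angle series")
    return float(knee[stance.start : stance.end].max())


def peak_vgrf_bw(vgrf: np.ndarray, stance: StanceSegment, mass: float) -> float:
    """Peak vertical force over the stance, in body weights."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if len(stance) < 1 or stance.end > len(vgrf):
        raise ValueError("empty or out-of-range stance")
    return float(np.max(vgrf[stance.start : stance.end]) / (mass * G))


def passive_peak_time(
    shank_vert_accel: np.ndarray,
    stance: StanceSegment,
    fs: float,
    search_fraction: float = 0.5,
) -> float:
    """Time (s from contact) of the early-stance shank acceleration peak.

    The impact event is located as the maximum absolute vertical shank
    acceleration within the first ``search_fraction`` of the stance — the
    accelerometer-based surrogate that also works for mid/forefoot strikers
    whose force curve has no distinct passive peak.
    """
    if len(stance) < 3:
        raise ValueError("stance too short (< 3 samples)")
    n_search = max(int(np.ceil(search_fraction * len(stance))), 1)
    window = np.abs(
        np.asarray(shank_vert_accel, dtype=float)[
            stance.start : stance.start + n_search
        ]
    )
    return float(np.argmax(window) / fs)


def loading_rate(
    vgrf: np.ndarray,
    fs: float,
    stance: StanceSegment,
    t_pp: float,
    mass: float,
) -> float:
    """vGRF slope between 20% and 80% of the passive-peak time, BW/s."""
    if not 0.0 < t_pp < len(stance) / fs:
        raise ValueError("t_pp must fall inside the stance")
    t0, t1 = 0.2 * t_pp, 0.8 * t_pp
    if (t1 - t0) * fs < 0.5:
        raise ValueError("t_pp too small to separate the 20%/80% points at fs")
    t_local = np.arange(len(vgrf)) / fs - stance.start / fs
    f0 = float(np.interp(t0, t_local, vgrf))
    f1 = float(np.interp(t1, t_local, vgrf))
    return (f1 - f0) / (t1 - t0) / (mass * G)


def bland_altman(
    est_values: Sequence[float], ref_values: Sequence[float]
) -> BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement of paired differences."""
    est = np.asarray(est_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("est and ref must be paired")
    if est.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = est - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(est + ref) / 2.0,
        differences=diff,
    )


def paired_ttest(
    est_values: Sequence[float],
    ref_values: Sequence[float],
    alpha: float = 0.05,
) -> Tuple[float, float, bool]:
    """Two-sided paired t-test; returns (t, p, significant at alpha)."""
    est = np.asarray(est_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if est.shape != ref.shape or est.size < 2:
        raise ValueError("need >= 2 pairs of equal length")
    diff = est - ref
    if np.ptp(diff) == 0:
        if np.allclose(diff, 0.0):
            return 0.0, 1.0, False
        raise ValueError("degenerate differences: zero variance, nonzero mean")
    res = stats.ttest_rel(est, ref)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def summarize_agreement(
    est_segments: Sequence[np.ndarray], ref_segments: Sequence[np.ndarray]
) -> AgreementSummary:
    """Per-segment rho and RMSE, aggregated across segments."""
    if len(est_segments) != len(ref_segments):
        raise ValueError("segment count mismatch")
    if not est_segments:
        raise ValueError("no segments to summarize")
    rhos = [pearson_rho(e, r) for e, r in zip(est_segments, ref_segments)]
    rmses = np.array([rmse(e, r) for e, r in zip(est_segments, ref_segments)])
    return AgreementSummary(
        rho_mean=fisher_mean_rho(rhos),
        rmse_mean=float(rmses.mean()),
        rmse_sd=float(rmses.std(ddof=1)) if len(rmses) > 1 else 0.0,
        n_segments=len(rmses),
    )
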