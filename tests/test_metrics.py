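"""Outcome-measure oracles: hand-computed and closed-form expectations."""

import numpy as np
import pytest

from imu2grf import (
    bland_altman,
    fisher_mean_rho,
    loading_rate,
    max_knee_flexion_stance,
    paired_ttest,
    passive_peak_time,
    peak_vgrf_bw,
    pearson_rho,
    rmse,
    summarize_agreement,
)
from imu2grf.preprocessing import StanceSegment
from imu2grf.synthetic import G, JointAngleSeries


def _stance(side="left", start=0, end=30, fs=120.0):
    return StanceSegment(side, start, end, start / fs)


class TestRmse:
    def test_perfect(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_value(self):
        assert rmse([2, 2, 2], [0, 2, 4]) == pytest.approx(np.sqrt(8 / 3), abs=1e-3)

    def test_single_pair(self):
        assert rmse([3.0], [1.0]) == 2.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1])


class TestPearson:
    def test_affine_relation(self):
        ref = np.array([1.0, 2, 3, 5, 8])
        assert pearson_rho(2 * ref + 1, ref) == pytest.approx(1.0)
        assert pearson_rho(-ref, ref) == pytest.approx(-1.0)

    def test_zero_covariance(self):
        assert pearson_rho([1, 2, 3, 4], [1, 2, 2, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_rho([1.0, 1.0, 1.0], [1, 2, 3])


class TestFisherMean:
    def test_idempotent_on_equal(self):
        assert fisher_mean_rho([0.8, 0.8]) == pytest.approx(0.8)

    def test_closed_form(self):
        """tanh(atanh(0.8)/2) = (3-1)/(3+1) = 0.5."""
        assert fisher_mean_rho([0.0, 0.8]) == pytest.approx(0.5)

    def test_singleton(self):
        assert fisher_mean_rho([0.37]) == pytest.approx(0.37)

    def test_between_min_and_max(self, rng):
        rhos = rng.uniform(-0.9, 0.99, 20)
        val = fisher_mean_rho(rhos)
        assert rhos.min() <= val <= rhos.max()

    def test_perfect_correlations_clipped(self):
        assert fisher_mean_rho([1.0, 1.0]) == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_mean_rho([])


class TestDiscreteOutcomes:
    def _angles(self, knee):
        n = len(knee)
        z = np.zeros(n)
        return JointAngleSeries(np.arange(n) / 120.0, z, np.asarray(knee, float), z, z, z, z)

    def test_constant_knee(self):
        angles = self._angles(np.full(50, 30.0))
        assert max_knee_flexion_stance(angles, _stance(end=40)) == 30.0

    def test_triangular_peak(self):
        knee = np.concatenate([np.linspace(0, 41, 20), np.linspace(41, 0, 20)])
        assert max_knee_flexion_stance(self._angles(knee), _stance(end=40)) == 41.0

    def test_generator_introspection(self):
        """Measured stance knee peak equals the configured template peak."""
        from imu2grf import (
            make_subject,
            preprocess_trial,
            segment_stances,
            simulate_trial,
        )

        s = make_subject(3)
        syn = preprocess_trial(simulate_trial(s, 12.0, 30.0, seed=3))
        stances = segment_stances(syn.vgrf_right, 120.0, side="right")
        peaks = [
            max_knee_flexion_stance(syn.ref_angles_imu, st) for st in stances
        ]
        assert np.mean(peaks) == pytest.approx(
            s.stance_knee_peak(12.0, "right"), abs=1.5
        )

    def test_peak_vgrf_bw(self):
        vgrf = np.zeros(50)
        vgrf[10] = 2060.1
        assert peak_vgrf_bw(vgrf, _stance(end=30), 70.0) == pytest.approx(3.0, abs=1e-3)
        vgrf[10] = 686.7
        assert peak_vgrf_bw(vgrf, _stance(end=30), 70.0) == pytest.approx(1.0, abs=1e-3)
        assert peak_vgrf_bw(np.zeros(50), _stance(end=30), 70.0) == 0.0


class TestPassivePeakTime:
    def test_single_impulse(self):
        fs = 1000.0
        accel = np.zeros(400)
        accel[100 + 25] = 50.0  # 25 ms after contact at sample 100
        st = StanceSegment("left", 100, 350, 0.1)
        assert passive_peak_time(accel, st, fs) == pytest.approx(0.025)

    def test_largest_early_impulse_wins(self):
        fs = 1000.0
        accel = np.zeros(400)
        accel[120] = 80.0  # 20 ms
        accel[200] = 50.0  # 100 ms
        st = StanceSegment("left", 100, 350, 0.1)
        assert passive_peak_time(accel, st, fs) == pytest.approx(0.020)

    def test_short_stance_rejected(self):
        with pytest.raises(ValueError):
            passive_peak_time(np.zeros(10), StanceSegment("left", 0, 2, 0.0), 120.0)


class TestLoadingRate:
    def test_linear_ramp(self):
        """F = 5000 t N, t_pp = 30 ms, 70 kg -> 5000/(70 g) = 7.28 BW/s."""
        fs = 1000.0
        t = np.arange(500) / fs
        vgrf = 5000.0 * t
        st = StanceSegment("left", 0, 400, 0.0)
        assert loading_rate(vgrf, fs, st, 0.030, 70.0) == pytest.approx(
            5000.0 / (70.0 * G), abs=1e-6
        )

    def test_constant_force_zero_slope(self):
        st = StanceSegment("left", 0, 100, 0.0)
        assert loading_rate(np.full(200, 900.0), 1000.0, st, 0.03, 70.0) == 0.0

    @pytest.mark.parametrize("t_pp", [0.02, 0.04, 0.08])
    @pytest.mark.parametrize("fs", [500.0, 1000.0])
    def test_slope_invariance(self, t_pp, fs):
        """An affine ramp's rate is independent of t_pp and sampling rate."""
        t = np.arange(int(fs)) / fs
        st = StanceSegment("left", 0, int(0.3 * fs), 0.0)
        val = loading_rate(3000.0 * t, fs, st, t_pp, 70.0)
        assert val == pytest.approx(3000.0 / (70.0 * G), rel=1e-9)

    def test_unresolvable_t_pp_rejected(self):
        st = StanceSegment("left", 0, 50, 0.0)
        with pytest.raises(ValueError):
            loading_rate(np.ones(100), 120.0, st, 0.003, 70.0)


class TestBlandAltman:
    def test_identical(self):
        res = bland_altman([1.0, 2, 3], [1.0, 2, 3])
        assert res.bias == 0 and res.loa_low == 0 and res.loa_high == 0

    def test_unit_sd(self):
        res = bland_altman([1.0, -1.0, 0.0], [0.0, 0.0, 0.0])
        assert res.bias == pytest.approx(0.0)
        assert res.loa_high == pytest.approx(1.96)
        assert res.loa_low == pytest.approx(-1.96)

    def test_constant_shift(self):
        res = bland_altman([3.0, 3.0], [1.0, 1.0])
        assert res.bias == res.loa_low == res.loa_high == 2.0

    def test_coverage_on_gaussian(self, rng):
        """LoA contain ~95% of differences (>= 90% with sampling slack)."""
        ref = rng.normal(size=5000)
        est = ref + rng.normal(scale=0.5, size=5000)
        res = bland_altman(est, ref)
        inside = (res.differences >= res.loa_low) & (res.differences <= res.loa_high)
        assert inside.mean() >= 0.90


class TestPairedTtest:
    def test_constructed_shift_significant(self, rng):
        ref = rng.normal(size=100)
        est = ref + 1.0 + rng.normal(scale=0.01, size=100)
        _, p, sig = paired_ttest(est, ref)
        assert sig and p < 1e-10

    def test_null_not_significant(self, rng):
        ref = rng.normal(size=100)
        est = ref + rng.normal(scale=0.3, size=100) * np.where(
            np.arange(100) % 2 == 0, 1, -1
        )
        _, p, sig = paired_ttest(est, ref)
        assert p > 0.05 and not sig

    def test_two_pairs_symmetric(self):
        t, p, sig = paired_ttest([1.0, -1.0], [0.0, 0.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert not sig

    def test_identical_pairs_degenerate(self):
        t, p, sig = paired_ttest([1.0, 2.0], [1.0, 2.0])
        assert (t, p, sig) == (0.0, 1.0, False)


class TestSummarizeAgreement:
    def test_identical_segments(self):
        seg = np.sin(np.linspace(0, 3, 40))
        out = summarize_agreement([seg, seg], [seg.copy(), seg.copy()])
        assert out.rho_mean == pytest.approx(1.0, abs=1e-9)
        assert out.rmse_mean == 0.0 and out.rmse_sd == 0.0

    def test_rmse_aggregation(self):
        ref = np.sin(np.linspace(0, 3, 100))
        est1 = ref + 1.0  # RMSE 1
        est3 = ref + 3.0  # RMSE 3
        out = summarize_agreement([est1, est3], [ref, ref])
        assert out.rmse_mean == pytest.approx(2.0)
        assert out.rmse_sd == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            summarize_agreement([np.arange(5.0)], [])


class TestTimeShiftInvariance:
    def test_common_shift_leaves_metrics_unchanged(self, rng):
        """Prepending the same lead-in to both signals moves the segment but
        not the metrics computed on it."""
        est = rng.normal(size=200).cumsum()
        ref = est + rng.normal(scale=0.1, size=200)
        pad = rng.normal(size=37)
        est_shifted = np.concatenate([pad, est])
        ref_shifted = np.concatenate([pad, ref])
        assert rmse(est_shifted[37:], ref_shifted[37:]) == rmse(est, ref)
        assert pearson_rho(est_shifted[37:], ref_shifted[37:]) == pearson_rho(est, ref)
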