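"""Generator contracts: determinism, population statistics, mechanics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from imu2grf import (
    forward_kinematics,
    joint_angle_trajectory,
    make_subject,
    simulate_trial,
    synthesize_accelerations,
    synthesize_vgrf,
)
from imu2grf.quaternions import qrotate
from imu2grf.synthetic import (
    G,
    JointAngleSeries,
    PelvisPose,
    extract_joint_angles,
)
from imu2grf import io as tio


class TestMakeSubject:
    def test_deterministic(self):
        a, b = make_subject(1), make_subject(1)
        assert a.mass == b.mass and a.duty_factor == b.duty_factor
        for j in ("hip", "knee", "ankle"):
            np.testing.assert_array_equal(
                a.angle_template_coeffs[j], b.angle_template_coeffs[j]
            )

    def test_override_passthrough(self):
        assert make_subject(1, overrides={"mass": 70.0}).mass == 70.0

    def test_unknown_override_rejected(self):
        with pytest.raises(ValueError, match="not_a_field"):
            make_subject(1, overrides={"not_a_field": 1.0})

    def test_population_band(self):
        """Cohort mean mass near the emulated runner population."""
        masses = [make_subject(i).mass for i in range(1, 9)]
        assert 77.7 - 9.4 <= np.mean(masses) <= 77.7 + 9.4

    def test_all_strike_types_in_cohort(self):
        strikes = {make_subject(i).strike_type for i in range(1, 9)}
        assert strikes == {"rearfoot", "midfoot", "forefoot"}


class TestJointAngleTrajectory:
    def test_periodic_boundary(self, subject):
        lo = joint_angle_trajectory(subject, 12.0, np.array([0.0]))
        hi = joint_angle_trajectory(subject, 12.0, np.array([1.0 - 1e-12]))
        np.testing.assert_allclose(lo.stack(), hi.stack(), atol=1e-6)

    def test_speed_must_be_positive(self, subject):
        with pytest.raises(ValueError):
            joint_angle_trajectory(subject, 0.0, np.array([0.1]))

    def test_stance_knee_peak_grows_with_speed(self):
        s = make_subject(3)
        assert s.stance_knee_peak(14.0) > s.stance_knee_peak(10.0)

    @pytest.mark.parametrize("seed", range(1, 9))
    def test_swing_peak_exceeds_stance_peak(self, seed):
        s = make_subject(seed)
        phase = np.linspace(0.0, 1.0, 2000, endpoint=False)
        knee = s.template_angle("knee", "right", 12.0, phase)
        stance_max = knee[phase < s.duty_factor].max()
        swing_max = knee[phase >= s.duty_factor].max()
        assert swing_max > stance_max


class TestForwardKinematics:
    def test_zero_angles_identity(self, subject):
        n = 4
        zeros = np.zeros(n)
        angles = JointAngleSeries(np.arange(n) / 240.0, *[zeros] * 6)
        quats, _ = forward_kinematics(subject, angles, PelvisPose.identity(n))
        for name, q in quats.items():
            np.testing.assert_allclose(q[:, 0], 1.0, atol=1e-12, err_msg=name)

    def test_right_angle_knee(self, subject):
        """Hip 0, knee 90 deg -> shank rotated 90 deg about the mediolateral axis."""
        n = 1
        z, k = np.zeros(n), np.full(n, 90.0)
        angles = JointAngleSeries(np.zeros(n), z, k, z, z, k, z)
        quats, _ = forward_kinematics(subject, angles, PelvisPose.identity(n))
        for side in ("left", "right"):
            rot = Rotation.from_quat(np.roll(quats[f"shank_{side}"][0], -1))
            rotvec = rot.as_rotvec(degrees=True)
            assert np.linalg.norm(rotvec) == pytest.approx(90.0, abs=1e-9)
            axis = rotvec / np.linalg.norm(rotvec)
            assert abs(axis[1]) == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_angles(self, subject, rng):
        """Sagittal angles are exactly recoverable from the chain quaternions."""
        n = 400
        angles = JointAngleSeries(
            np.arange(n) / 240.0,
            rng.uniform(-20, 40, n),
            rng.uniform(0, 100, n),
            rng.uniform(-20, 20, n),
            rng.uniform(-20, 40, n),
            rng.uniform(0, 100, n),
            rng.uniform(-20, 20, n),
        )
        pose = PelvisPose.identity(n)
        pose.quat = np.roll(
            Rotation.from_euler(
                "xy", rng.uniform(-10, 10, (n, 2)), degrees=True
            ).as_quat(),
            1,
            axis=-1,
        )
        pose.hip_ab_left = rng.uniform(-6, 6, n)
        pose.hip_ab_right = rng.uniform(-6, 6, n)
        quats, _ = forward_kinematics(subject, angles, pose)
        recovered = extract_joint_angles(quats, angles.time)
        assert np.abs(recovered.stack() - angles.stack()).max() < 1e-6


class TestSynthesizeVgrf:
    def test_flight_reaches_zero(self, subject):
        fl, fr = synthesize_vgrf(subject, 12.0, 10.0)
        assert fl.min() == 0.0 and fr.min() == 0.0

    def test_peak_equals_configured_multiple(self):
        s = make_subject(1, overrides={"mass": 70.0, "peak_vgrf_multiple": 3.0})
        fl, _ = synthesize_vgrf(s, 12.0, 30.0)
        assert fl.max() == pytest.approx(3.0 * 70.0 * G, rel=1e-3)

    @pytest.mark.parametrize("seed", [1, 3, 5])
    def test_impulse_balance(self, seed):
        """Time-averaged total force over whole strides equals body weight."""
        s = make_subject(seed)
        fl, fr = synthesize_vgrf(s, 12.0, 60.0, 1000.0)
        n = int(np.floor(60.0 * s.stride_frequency(12.0)) / s.stride_frequency(12.0) * 1000)
        ratio = (fl[:n] + fr[:n]).mean() / (s.mass * G)
        assert 0.98 <= ratio <= 1.02

    def test_low_rate_rejected(self, subject):
        with pytest.raises(ValueError):
            synthesize_vgrf(subject, 12.0, 10.0, fs=100.0)


class TestSynthesizeAccelerations:
    def test_static_sensor_reads_gravity(self):
        n = 50
        q = np.zeros((n, 4))
        q[:, 0] = 1.0
        out = synthesize_accelerations(
            {"pelvis": np.zeros((n, 3))}, {"pelvis": q}, 240.0
        )
        np.testing.assert_allclose(
            out["pelvis"][2:-2], np.tile([0.0, 0.0, G], (46, 1)), atol=1e-9
        )

    def test_vertical_oscillation_analytic(self):
        """z = A sin(2 pi f t) => vertical specific force g - A w^2 sin."""
        fs, amp, f = 1000.0, 0.03, 3.0
        t = np.arange(5000) / fs
        pos = np.zeros((len(t), 3))
        pos[:, 2] = amp * np.sin(2 * np.pi * f * t)
        q = np.zeros((len(t), 4))
        q[:, 0] = 1.0
        out = synthesize_accelerations({"s": pos}, {"s": q}, fs)
        expected = G - amp * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t)
        np.testing.assert_allclose(out["s"][5:-5, 2], expected[5:-5], atol=1e-3)

    def test_noise_deterministic(self, rng):
        n = 100
        pos = {"s": rng.normal(size=(n, 3))}
        q = np.zeros((n, 4))
        q[:, 0] = 1.0
        a = synthesize_accelerations(pos, {"s": q}, 240.0, noise=0.5, seed=7)
        b = synthesize_accelerations(pos, {"s": q}, 240.0, noise=0.5, seed=7)
        np.testing.assert_array_equal(a["s"], b["s"])

    def test_length_mismatch_rejected(self):
        q = np.zeros((5, 4))
        q[:, 0] = 1.0
        with pytest.raises(ValueError):
            synthesize_accelerations({"s": np.zeros((6, 3))}, {"s": q}, 240.0)


class TestSimulateTrial:
    def test_stream_lengths(self, subject):
        tr = simulate_trial(subject, 12.0, 60.0, seed=0)
        assert len(tr.force_left) == 60000
        assert len(tr.quat_pelvis) == 14400

    def test_bit_identical_repeat(self, subject):
        a = simulate_trial(subject, 12.0, 12.0, seed=5)
        b = simulate_trial(subject, 12.0, 12.0, seed=5)
        np.testing.assert_array_equal(a.force_left, b.force_left)
        np.testing.assert_array_equal(a.quat_shank_left, b.quat_shank_left)
        np.testing.assert_array_equal(a.accel_pelvis, b.accel_pelvis)

    def test_optical_reference_offset(self, raw_trial):
        """Optical-like knee reference differs smoothly by at most a few deg."""
        diff = raw_trial.ref_angles_optical.left_knee - raw_trial.ref_angles_imu.left_knee
        assert 0.0 < np.abs(diff).mean() <= 5.0
        diff_r = raw_trial.ref_angles_optical.right_knee - raw_trial.ref_angles_imu.right_knee
        assert 0.0 < np.abs(diff_r).mean() <= 5.0

    def test_minimum_duration_enforced(self, subject):
        with pytest.raises(ValueError):
            simulate_trial(subject, 12.0, 5.0, seed=0)

    def test_impact_colocated_with_passive_transient(self, rearfoot_subject):
        """Shank accel spike occurs at the passive-transient time of each stance."""
        s = rearfoot_subject
        tr = simulate_trial(s, 12.0, 30.0, seed=1)
        acc = qrotate(tr.quat_shank_right, tr.accel_shank_right)[:, 2] - G
        f_str = s.stride_frequency(12.0)
        t_stance = s.duty_factor / f_str
        t = np.arange(len(acc)) / tr.imu_rate
        deviations = []
        for k in range(2, int(30.0 * f_str) - 2):
            tc = k / f_str
            win = (t >= tc) & (t < tc + 0.5 * t_stance)
            t_peak = t[win][np.argmax(np.abs(acc[win]))]
            deviations.append(abs(t_peak - (tc + s.t_passive)))
        assert max(deviations) <= 0.010


class TestTrialCsvRoundTrip:
    def test_round_trip(self, subject, tmp_path):
        tr = simulate_trial(subject, 12.0, 10.0, seed=2)
        tio.write_trial_csv(tr, tmp_path, "t")
        back = tio.read_trial_csv(tmp_path, "t", subject, 12.0)
        np.testing.assert_allclose(back.force_left, tr.force_left, atol=1e-6)
        np.testing.assert_allclose(back.quat_pelvis, tr.quat_pelvis, atol=1e-10)
        np.testing.assert_allclose(
            back.ref_angles_optical.right_knee, tr.ref_angles_optical.right_knee,
            atol=1e-6,
        )

    def test_subject_json_round_trip(self, subject, tmp_path):
        tio.write_subject_json(subject, tmp_path / "s.json")
        back = tio.read_subject_json(tmp_path / "s.json")
        assert back.mass == subject.mass
        assert back.strike_type == subject.strike_type
        np.testing.assert_allclose(
            back.angle_template_coeffs["knee"], subject.angle_template_coeffs["knee"]
        )
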