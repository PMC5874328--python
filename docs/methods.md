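# Methods

`imu2grf` estimates sagittal lower-body joint angles and vertical ground
reaction forces (vGRF) during treadmill running from three inertial
measurement units (IMUs) — one on the pelvis and one on each lower leg —
using two concatenated feed-forward neural networks. Because the kind of
laboratory dataset this method is validated on (synchronized full-body
motion capture, instrumented treadmill) is rarely shareable, the package
ships a synthetic treadmill-running generator with the statistical and
mechanical structure the method relies on, and validates the whole pipeline
end to end on it.

## The estimation model

**Stage 1 (orientation network).** The input at each 120 Hz sample is the
orientation of each shank expressed in the pelvis frame,
`q_rel = conj(q_pelvis) ⊗ q_shank`, as unit quaternions (Hamilton
convention, scalar first) made sign-continuous in time — 8 features. The
output is the six sagittal joint angles (hip, knee, ankle flexion/extension,
both sides) in degrees. The mapping is per-sample: no temporal window, no
delay line.

**Stage 2 (force network).** The input combines the estimated joint angles
with the vertical components, in the global frame, of the free sensor
accelerations (specific force rotated by the sensor orientation, gravity
removed; g = 9.81 m/s²). Five feature combinations are supported: pelvis
acceleration only (`a_p`, 1 column), all three accelerations (`a_pl`, 3),
joint angles only (`theta`, 6), and the two combinations (`a_p_theta` 7,
`a_pl_theta` 9, the default). The output is left and right vGRF in body
weights (BW); predictions are clipped at 0 BW.

Stage 2 is trained on stage 1's *estimated* joint angles — the same signals
it will see at inference — so it learns to tolerate the orientation
network's error structure; the deployed pipeline needs only the three IMUs.
This choice matters on synthetic data: the reference angles are noise-free,
and a force network trained on them becomes brittle to stage-1 noise
exactly where the force curve is sharpest (the impact transient), inflating
vGRF errors severalfold for noise-sensitive gaits. Training on reference
angles instead is available via `ann2_train_on="reference"`.

Both networks share one architecture: 250 and 100 tanh hidden units, linear
output, full-batch mean-squared-error minimisation with inputs and targets
mapped per column onto [-1, 1] by their training minimum/maximum (stored
with the model, so inference is self-contained; constant columns map to 0
and are flagged). Weights start from fan-in-scaled uniform noise, seeded.

### Optimisation and stopping

Minimisation uses L-BFGS with a strong-Wolfe line search, so the recorded
per-iteration training loss is non-increasing (asserted with 1e-9 slack in
the tests). Training stops at the first of:

- 2000 iterations;
- infinity-norm of the gradient below 1e-6;
- 6 consecutive iterations in which the stopping metric fails to improve on
  its best value so far ("patience").

The default stopping metric is the mean-squared error on a held-out
validation split (15% of rows, seeded shuffle) — the behaviour of the
classical neural-network toolboxes this training protocol descends from. A
gradient-norm stagnation counter is available via
`TrainConfig(stopping="gradient")`; under L-BFGS the gradient norm is highly
oscillatory, which makes that variant stop very early, so the validation
counter is the default.

Networks compute in float32 internally (losses and gradients are reported
in float64): the objective is memory-bandwidth bound and the scaled tanh
regression is insensitive to precision beyond ~1e-6. Everything is
deterministic given `TrainConfig.seed`.

### Training-set thinning

A 50 s trial at 120 Hz contains ~70 near-periodic strides; feature rows far
exceed the information content. `ConcatenatedEstimator` therefore thins
training matrices larger than `max_train_samples` (default 5 000 rows, both
stages) by taking every k-th row. Because stride period and thinning step are
incommensurate, the retained rows still cover the gait cycle densely. This
is a problem-size choice, not a model choice; set
`max_train_samples=None` to disable.

## The synthetic cohort

`make_subject(seed)` draws one runner: mass ~ N(77.7, 9.4) kg and height
~ N(1.837, 0.045) m (a healthy adult male recreational-runner population),
segment lengths proportional to height, cadence 80–88 strides/min at
12 km/h with +1.2%/km/h, duty factor (stance fraction of the stride)
U(0.26, 0.32), and a foot-strike pattern from a fixed 5 rear / 2 mid /
1 fore pattern indexed by `seed mod 8` — the published distribution of
strike types in runners is broad, and this fixed mix guarantees a cohort of
seeds 1..8 contains all three patterns.

**Kinematics.** Each joint has a per-subject periodic template, stored as
13 Fourier harmonics of a stride-phase waveform: the knee combines a stance
flexion bump (peak 33–43° near 13% of the stride) and a larger swing bump
(88–104° near 67%), hip and ankle are low-harmonic sinusoid mixtures.
Template amplitude scales linearly with belt speed (knee ≈ +1.3–2.1%/km/h),
reproducing the usual growth of stance knee flexion from 10 to 14 km/h.
The left leg runs the same template shifted half a stride, times a small
subject-specific gain (±3%) and timing (±0.4% stride) asymmetry. A
forward-kinematics chain (pelvis pose with vertical excursion, pitch/roll
oscillation and small hip ab/adduction; then hip → knee → ankle rotations
about the mediolateral axis) produces segment quaternions and sensor
positions. The sagittal angles are *exactly* recoverable from these
quaternions (round trip < 1e-6°), which guarantees stage 1's regression
target is a true function of its inputs; a nearest-neighbour oracle on
noise-free data confirms the inverse map is learnable (knee RMSE < 0.5°).

**Kinetics.** Each stance is an active hump
`F(s) = peak · BW · (4 s (1 − s))^p` over stance fraction s, with the
subject's peak multiple in ~2.6–3.2 BW. The exponent p is solved per
subject from steady-state impulse balance — the time-average of the total
vGRF over whole strides must equal body weight — so the generator is
mechanically consistent by construction (verified to ±2%). The hump's
near-linear onset also makes the 20 N threshold recover the duty factor to
±0.02 despite the 20 Hz low-pass. Rearfoot strikers additionally get a
passive (impact) transient: a 0.5 BW Gaussian bump (σ = 9 ms) centred
19–27 ms after contact, windowed to vanish at the stance edges; mid/forefoot
strikers have a monotone rise, mirroring the fact that their impact peak is
not distinct in the force trace.

**Accelerometry.** Specific force is the second central difference of the
sensor position plus gravity, rotated into the sensor frame. Shank
positions receive a sharp vertical dip at each ipsilateral contact whose
curvature peaks at the passive-transient time (~13 g for rearfoot, ~4 g
otherwise), so the accelerometer-based impact-event detector and the force
transient are co-located in absolute time — the property the loading-rate
landmark depends on.

**Noise and references.** Defaults: orientation white noise 0.5° (as a
random rotation per sample), acceleration 0.2 m/s², force 5 N clipped at
0 N. Besides the ground-truth (inertial-like) reference angles, each trial
carries an optical-like variant: the truth plus a smooth periodic
subject-specific offset (constant + first harmonic, ≤ 5°) and 0.25° noise,
emulating the systematic model differences between marker-based and
inertial kinematics.

**What the generator does not emulate.** Soft-tissue artefact dynamics,
orientation drift and magnetic disturbance, treadmill-belt speed
fluctuation, stride-to-stride variability beyond white noise (the
underlying gait limit cycle is exactly periodic), fatigue, and any
non-sagittal kinetics. Passing the synthetic validation therefore shows the
pipeline is implemented correctly and has the capacity to learn mappings of
this structure — not that a real cohort would reach the same accuracy.

## Processing pipeline

1. **Crop** a configurable head/tail (default 5 s) to drop treadmill
   spin-up/down.
2. **Filter** each vGRF channel with a zero-phase 6th-order Butterworth
   low-pass at 20 Hz (`filtfilt`, reflective padding of 3 filter lengths;
   effective 12th-order magnitude, DC gain 1, amplitude 0.5 at the cutoff);
   clip negatives to 0.
3. **Resample** everything to one 120 Hz grid: 240 Hz IMU streams by
   picking every 2nd sample; 1000 Hz force by linear interpolation (the
   ratio is non-integer, and the 20 Hz filter already guarantees
   anti-aliasing far below the 60 Hz Nyquist). Quaternions are made
   sign-continuous before interpolation and re-normalised after.
4. **Segment** stance phases as maximal runs of vGRF ≥ 20 N, with a 50 ms
   debounce (shorter runs dropped, shorter gaps merged — filter ripple near
   the threshold would otherwise double-trigger) and boundary-touching
   contacts discarded as incomplete. Strides run from one ipsilateral
   contact to the next; the stance sits at the head of its stride.

## Outcome measures

Continuous agreement is computed per stride (knee angles) and per stance
(vGRF, since there is no force outside contact): Pearson's ρ per segment,
averaged through the Fisher z-transform (ρ clipped to ±(1−1e-12) before
atanh), and unnormalised RMSE (mean ± SD across segments; a range-normalised
variant is a flag away). Discrete outcomes per stance: maximum knee flexion;
peak vGRF in BW; the passive-peak time, located as the maximum absolute
shank vertical acceleration in the first half of stance (the
accelerometer-based surrogate that also works for mid/forefoot strikers);
and the loading rate, the vGRF slope between 20% and 80% of the
passive-peak time (linear interpolation at off-grid times, contact-relative
clock), in BW/s. Method comparison uses two-sided paired t-tests (α = 0.05,
no multiplicity correction) and Bland–Altman bias with 1.96·SD limits of
agreement.

Evaluation always segments on the measured (reference) force, and the
passive-peak time from the measured accelerometer is shared by the
reference and estimated loading-rate computations, so the discrete-outcome
comparison isolates the force-curve estimate itself. Note that the 20 N
threshold on 20 Hz-filtered data detects contact slightly early for
rearfoot strikers (the filter spreads the impact transient backwards);
both the estimate and the reference see the same segmentation, so
agreement metrics are unaffected.

## Evaluation scenarios

- **Single-subject:** train on one subject's 10 and 14 km/h trials,
  evaluate on the held-out 12 km/h trial. The personalised mode.
- **Leave-one-subject-out (LOSO):** train on all trials (all speeds) of
  the other subjects, evaluate on the held-out subject's 12 km/h trial.
  Degrades with gait-style diversity — the forefoot striker is the
  hardest hold-out, as expected.
- **Feature ablation:** the single-subject scenario per feature set,
  sharing the trained stage-1 network and seeds across sets.
- **Speed generalization:** leave-one-speed-out; the interpolated middle
  speed is estimated best.

The canonical experiment (`imu2grf.experiments.run_headline_experiment`)
uses 8 subjects × {10, 12, 14} km/h × 60 s per trial. Sixty seconds
(~70 complete strides after cropping) rather than a 3-minute session keeps
the whole experiment at desk scale; stride count, not wall duration, drives
both learnability and metric stability. The simulator accepts any duration.

## Numerical choices and edge cases

- One rotation convention everywhere: global frame Z-up, gravity −Z,
  Hamilton quaternions, scalar first, sensor-to-global. Accelerometer
  channels carry specific force (gravity included) in the sensor frame —
  what a physical IMU measures; gravity removal happens in the feature
  layer.
- Quaternion double cover: series are forced to non-negative consecutive
  dot products, first element scalar ≥ 0.
- Degenerate inputs are errors, not NaNs: constant sequences in Pearson
  correlation, empty correlation lists, zero-variance non-zero-mean
  differences in the paired t-test, stances shorter than 3 samples,
  passive-peak times too small to separate the 20%/80% points at the
  sampling rate.
- Seeds: the simulator seed and the training seed are independent; every
  derived seed comes from `numpy.random.SeedSequence` and stays below 2³¹.
  Identical seeds give bit-identical trials, weights and reports.
- Model files are single `.npz` archives with a version tag
  (`imu2grf-model-v1`); loading a truncated or foreign file raises, and a
  save/load round trip reproduces predictions bit-exactly.

## Known limitations

- Only sagittal kinematics and vertical force; no 3-D GRF, no frontal or
  transverse angles.
- Per-sample mapping cannot exploit temporal context; a recurrent or
  windowed variant is out of scope.
- The synthetic cohort's LOSO difficulty is governed by the configured
  inter-subject variation; real inter-subject variability (landing
  mechanics, soft-tissue artefact) is richer.
- The passive-peak detector assumes the impact spike dominates early-stance
  shank acceleration; for very smooth accelerations (non-rearfoot subjects)
  it returns the largest early-stance feature instead of a true impact
  event, which is the intended surrogate behaviour but not a validated
  impact measurement.
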