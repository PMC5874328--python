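"""Function-fitting networks and the concatenated estimator.

Both stages use the same architecture: a two-hidden-layer feed-forward
network (250 and 100 tanh units, linear output) trained full-batch on
mean-squared error with inputs and targets mapped to [-1, 1] by their
training min/max. Minimisation uses L-BFGS (strong-Wolfe line search, so the
recorded loss history is non-increasing), and training stops at 2000
iterations, when the gradient norm falls below 1e-6, or after 6 consecutive
iterations without improvement of the stopping metric — by default the
validation mean-squared error (classic toolbox behaviour); a gradient-norm
stagnation counter is available via ``stopping="gradient"``.

:class:`ConcatenatedEstimator` chains the two stages: the orientation
network (ANN_1) maps pelvis-relative shank quaternions to the six sagittal
joint angles; the force network (ANN_2) maps those angles plus global-frame
vertical sensor accelerations to left/right vGRF in body weights. ANN_2
trains on ANN_1's estimated angles (so it learns to tolerate the first
stage's error structure) and consumes them at inference; the deployed
pipeline needs no force plate. Training on reference angles instead is
available via ``ann2_train_on="reference"``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

from . import features as ft
from .preprocessing import SyncedTrial
from .synthetic import JointAngleSeries

MODEL_FORMAT_VERSION = "imu2grf-model-v1"


@dataclass
class TrainConfig:
    """Training protocol of one network."""

    hidden_sizes: Tuple[int, int] = (250, 100)
    max_iterations: int = 2000
    grad_tolerance: float = 1e-6
    patience: int = 6
    seed: int = 0
    validation_fraction: float = 0.15
    stopping: str = "validation"  # 'validation' | 'gradient'

    def __post_init__(self):
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.grad_tolerance <= 0:
            raise ValueError("grad_tolerance must be positive")
        if not 0.0 <= self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must lie in [0, 0.5)")
        if self.stopping not in ("gradient", "validation"):
            raise ValueError("stopping must be 'gradient' or 'validation'")


class _EarlyStop(Exception):
    def __init__(self, reason: str):
        self.reason = reason


class FeedforwardRegressor(BaseEstimator, RegressorMixin):
    """Two-hidden-layer tanh regression network with min-max scaling.

    Parameters mirror :class:`TrainConfig`. Fitted attributes:

    - ``coefs_``, ``intercepts_``: layer weights/biases (in -> h1 -> h2 -> out)
    - ``input_scaler_``, ``output_scaler_``: [-1, 1] min-max states
    - ``loss_history_``, ``grad_history_``: per-iteration objective and
      gradient norm (scaled space)
    - ``n_iter_``, ``stop_reason_``
    """

    def __init__(
        self,
        hidden_sizes: Tuple[int, int] = (250, 100),
        max_iterations: int = 2000,
        grad_tolerance: float = 1e-6,
        patience: int = 6,
        seed: int = 0,
        validation_fraction: float = 0.15,
        stopping: str = "validation",
    ):
        self.hidden_sizes = hidden_sizes
        self.max_iterations = max_iterations
        self.grad_tolerance = grad_tolerance
        self.patience = patience
        self.seed = seed
        self.validation_fraction = validation_fraction
        self.stopping = stopping

    # -- parameter vector packing ------------------------------------------
    def _shapes(self, d_in: int, d_out: int):
        h1, h2 = self.hidden_sizes
        return [(d_in, h1), (h1,), (h1, h2), (h2,), (h2, d_out), (d_out,)]

    @staticmethod
    def _unpack(theta: np.ndarray, shapes):
        out, i = [], 0
        for s in shapes:
            n = int(np.prod(s))
            out.append(theta[i : i + n].reshape(s))
            i += n
        return out

    @staticmethod
    def _forward(params, x):
        w1, b1, w2, b2, w3, b3 = params
        z1 = np.tanh(x @ w1 + b1)
        z2 = np.tanh(z1 @ w2 + b2)
        return z1, z2, z2 @ w3 + b3

    def _loss_grad(self, theta, shapes, x, y):
        # training runs in float32: the objective is memory-bandwidth bound
        # and min-max-scaled tanh regression never needs 1e-16 resolution
        params = self._unpack(np.asarray(theta, dtype=x.dtype), shapes)
        w1, b1, w2, b2, w3, b3 = params
        n = len(x)
        z1, z2, yhat = self._forward(params, x)
        err = yhat.astype(np.float64) - y
        loss = 0.5 * float(np.mean(err**2))
        err = err.astype(x.dtype)
        # mean over samples*outputs
        d3 = err / (n * y.shape[1])
        g_w3 = z2.T @ d3
        g_b3 = d3.sum(axis=0)
        d2 = (d3 @ w3.T) * (1.0 - z2**2)
        g_w2 = z1.T @ d2
        g_b2 = d2.sum(axis=0)
        d1 = (d2 @ w2.T) * (1.0 - z1**2)
        g_w1 = x.T @ d1
        g_b1 = d1.sum(axis=0)
        grad = np.concatenate(
            [g.ravel() for g in (g_w1, g_b1, g_w2, g_b2, g_w3, g_b3)]
        )
        return loss, grad.astype(np.float64)

    def fit(self, X, y):
        x = np.asarray(getattr(X, "values", X), dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if x.ndim != 2 or len(x) != len(y):
            raise ValueError("X and y must be 2-d with matching row counts")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in training data")

        self.input_scaler_ = ft.fit_scaler(x)
        self.output_scaler_ = ft.fit_scaler(y)
        xs = ft.apply_scaler(x, self.input_scaler_).astype(np.float32)
        ys = ft.apply_scaler(y, self.output_scaler_).astype(np.float32)

        xs_val = ys_val = None
        if self.stopping == "validation" and self.validation_fraction > 0:
            rng_split = np.random.default_rng(
                np.random.SeedSequence([53, int(self.seed)])
            )
            n_val = int(round(self.validation_fraction * len(xs)))
            if n_val >= 1:
                idx = rng_split.permutation(len(xs))
                xs_val, ys_val = xs[idx[:n_val]], ys[idx[:n_val]]
                xs, ys = xs[idx[n_val:]], ys[idx[n_val:]]

        d_in, d_out = xs.shape[1], ys.shape[1]
        shapes = self._shapes(d_in, d_out)
        rng = np.random.default_rng(np.random.SeedSequence([17, int(self.seed)]))
        theta0 = np.concatenate(
            [
                (rng.uniform(-1.0, 1.0, int(np.prod(s))) / np.sqrt(s[0]))
                if len(s) == 2
                else np.zeros(int(np.prod(s)))
                for s in shapes
            ]
        )

        loss_hist: List[float] = []
        grad_hist: List[float] = []
        state = {"count": 0, "best": np.inf, "prev": np.inf, "reason": "max_iterations"}
        last = {"theta": theta0}

        def objective(theta):
            last["theta"] = np.array(theta, copy=True)
            return self._loss_grad(theta, shapes, xs, ys)

        def callback(theta):
            last["theta"] = np.array(theta, copy=True)
            loss, grad = self._loss_grad(theta, shapes, xs, ys)
            gnorm = float(np.linalg.norm(grad, np.inf))
            loss_hist.append(loss)
            grad_hist.append(gnorm)
            if gnorm < self.grad_tolerance:
                raise _EarlyStop("grad_tolerance")
            if self.stopping == "gradient":
                metric = gnorm
            else:
                params = self._unpack(theta, shapes)
                if xs_val is not None:
                    err = self._forward(params, xs_val)[2].astype(np.float64) - ys_val
                    metric = 0.5 * float(np.mean(err**2))
                else:
                    metric = loss
            # stagnation counter: `patience` consecutive iterations without a
            # new best (decrease) of the stopping metric
            if metric < state["best"]:
                state["best"] = metric
                state["count"] = 0
            else:
                state["count"] += 1
                if state["count"] >= self.patience:
                    raise _EarlyStop(self.stopping)

        try:
            res = minimize(
                objective,
                theta0,
                method="L-BFGS-B",
                jac=True,
                callback=callback,
                options={
                    "maxiter": self.max_iterations,
                    "gtol": 0.0,
                    "ftol": 0.0,
                    "maxls": 40,
                },
            )
            theta = res.x
            if len(loss_hist) >= self.max_iterations:
                state["reason"] = "max_iterations"
            else:
                state["reason"] = "converged"
        except _EarlyStop as stop:
            # scipy does not hand the final iterate to the exception path;
            # the objective closure tracked it
            state["reason"] = stop.reason
            theta = last["theta"]

        params = self._unpack(theta, shapes)
        self.coefs_ = [params[0], params[2], params[4]]
        self.intercepts_ = [params[1], params[3], params[5]]
        self.loss_history_ = np.asarray(loss_hist)
        self.grad_history_ = np.asarray(grad_hist)
        self.n_iter_ = len(loss_hist)
        self.stop_reason_ = state["reason"]
        self.n_features_in_ = d_in
        self.n_outputs_ = d_out
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coefs_"):
            raise RuntimeError("model is not fitted")
        x = np.asarray(getattr(X, "values", X), dtype=float)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {x.shape[1]} columns, model expects {self.n_features_in_}"
            )
        xs = ft.apply_scaler(x, self.input_scaler_)
        params = [
            self.coefs_[0], self.intercepts_[0],
            self.coefs_[1], self.intercepts_[1],
            self.coefs_[2], self.intercepts_[2],
        ]
        ys = self._forward(params, xs)[2]
        y = ft.invert_scaler(ys, self.output_scaler_)
        return y[0] if single else y


MLPModel = FeedforwardRegressor


def train_mlp(X, Y, config: Optional[TrainConfig] = None) -> FeedforwardRegressor:
    """Train one network under the standard protocol (>= 100 samples)."""
    config = config or TrainConfig()
    x = np.asarray(getattr(X, "values", X), dtype=float)
    if len(x) < 100:
        raise ValueError("need at least 100 training samples")
    est = FeedforwardRegressor(**dataclasses.asdict(config))
    return est.fit(X, Y)


def predict(model: FeedforwardRegressor, X) -> np.ndarray:
    """Apply a trained network (schema-checked)."""
    names = getattr(X, "column_names", None)
    if names is not None and len(names) != model.n_features_in_:
        raise ValueError(
            f"feature columns {list(names)} do not match model input width "
            f"{model.n_features_in_}"
        )
    return model.predict(X)


class ConcatenatedEstimator(BaseEstimator):
    """ANN_1 (orientations -> angles) chained into ANN_2 (-> vGRF in BW).

    ``scheme`` selects the kinematic reference used as ANN_1's target ('imu'
    or 'optical'); ``feature_set`` selects ANN_2's inputs. ANN_2 trains on
    ANN_1's estimated angles by default (``ann2_train_on='estimated'``) and
    always consumes ANN_1's estimates at inference. Training matrices larger than
    ``max_train_samples`` rows are deterministically thinned (every k-th
    sample) to keep multi-subject fits tractable.
    """

    def __init__(
        self,
        scheme: str = "imu",
        feature_set: str = "a_pl_theta",
        config: Optional[TrainConfig] = None,
        ann2_train_on: str = "estimated",
        max_train_samples: Optional[int] = 5000,
    ):
        self.scheme = scheme
        self.feature_set = feature_set
        self.config = config
        self.ann2_train_on = ann2_train_on
        self.max_train_samples = max_train_samples

    def _thin(self, x: np.ndarray, y: np.ndarray):
        if self.max_train_samples and len(x) > self.max_train_samples:
            step = int(np.ceil(len(x) / self.max_train_samples))
            return x[::step], y[::step]
        return x, y

    def fit(
        self,
        trials: Sequence[SyncedTrial],
        ann1: Optional[FeedforwardRegressor] = None,
    ):
        """Train both stages; pass ``ann1`` to reuse a fitted stage 1
        (the orientation network is independent of ANN_2's feature set)."""
        if not trials:
            raise ValueError("need at least one training trial")
        if self.scheme not in ("imu", "optical"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.ann2_train_on not in ("reference", "estimated"):
            raise ValueError("ann2_train_on must be 'reference' or 'estimated'")
        fset = ft.FEATURE_SETS.get(self.feature_set)
        if fset is None:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        config = self.config or TrainConfig()

        if ann1 is not None:
            self.ann1_ = ann1
            n1 = -1
        else:
            io1 = [ft.build_ann1_io(t, self.scheme) for t in trials]
            x1 = np.concatenate([xm.values for xm, _ in io1])
            y1 = np.concatenate([y for _, y in io1])
            x1, y1 = self._thin(x1, y1)
            self.ann1_ = train_mlp(x1, y1, config)
            n1 = len(x1)

        xy2 = []
        for t in trials:
            if self.ann2_train_on == "reference":
                angles = t.ref_angles(self.scheme)
            else:
                angles = self._estimate_angles(t)
            xm, y = ft.build_ann2_io(angles, t, fset)
            xy2.append((xm.values, y))
        x2 = np.concatenate([a for a, _ in xy2])
        y2 = np.concatenate([b for _, b in xy2])
        x2, y2 = self._thin(x2, y2)
        cfg2 = dataclasses.replace(config, seed=config.seed + 1)
        self.ann2_ = train_mlp(x2, y2, cfg2)

        self.metadata_ = {
            "scheme": self.scheme,
            "feature_set": self.feature_set,
            "ann2_train_on": self.ann2_train_on,
            "subjects": sorted({t.subject.subject_id for t in trials}),
            "speeds": sorted({float(t.speed) for t in trials}),
            "n_train_samples": [int(n1), int(len(x2))],
        }
        return self

    def _estimate_angles(self, trial: SyncedTrial) -> JointAngleSeries:
        xm, _ = ft.build_ann1_io(trial, "imu")
        pred = self.ann1_.predict(xm.values)
        return JointAngleSeries.from_array(trial.time, pred)

    def estimate(
        self, trial: SyncedTrial
    ) -> Tuple[JointAngleSeries, np.ndarray]:
        """Deployment path: angles and vGRF (BW, clipped at 0) from IMUs only."""
        if not hasattr(self, "ann1_"):
            raise RuntimeError("estimator is not fitted")
        angles = self._estimate_angles(trial)
        fset = ft.FEATURE_SETS[self.feature_set]
        accel = {
            "a_pelvis": (trial.quat_pelvis, trial.accel_pelvis),
            "a_shank_left": (trial.quat_shank_left, trial.accel_shank_left),
            "a_shank_right": (trial.quat_shank_right, trial.accel_shank_right),
        }
        theta = dict(zip(ft.THETA_COLUMNS, angles.stack().T))
        cols = []
        for name in fset.columns:
            if name in accel:
                q, f = accel[name]
                cols.append(ft.global_vertical_acceleration(q, f))
            else:
                cols.append(theta[name])
        vgrf_bw = np.clip(self.ann2_.predict(np.stack(cols, axis=-1)), 0.0, None)
        return angles, vgrf_bw

    def predict(self, trial: SyncedTrial) -> np.ndarray:
        return self.estimate(trial)[1]


def build_estimator(
    train_trials: Sequence[SyncedTrial],
    scheme: str = "imu",
    feature_set: str = "a_pl_theta",
    config: Optional[TrainConfig] = None,
    **kwargs,
) -> ConcatenatedEstimator:
    """Train the two-stage estimator on synchronized trials."""
    est = ConcatenatedEstimator(
        scheme=scheme, feature_set=feature_set, config=config, **kwargs
    )
    return est.fit(train_trials)


def estimate(
    estimator: ConcatenatedEstimator, trial: SyncedTrial
) -> Tuple[JointAngleSeries, np.ndarray]:
    return estimator.estimate(trial)


def _scaler_arrays(prefix: str, s: ft.ScalerState) -> dict:
    return {
        f"{prefix}_lo": s.lo,
        f"{prefix}_hi": s.hi,
        f"{prefix}_degenerate": s.degenerate,
    }


def _scaler_from(archive, prefix: str) -> ft.ScalerState:
    return ft.ScalerState(
        lo=archive[f"{prefix}_lo"],
        hi=archive[f"{prefix}_hi"],
        degenerate=archive[f"{prefix}_degenerate"],
    )


def save_estimator(estimator: ConcatenatedEstimator, path) -> None:
    """Persist weights, scalers, config and metadata to one .npz archive."""
    if not hasattr(estimator, "ann1_"):
        raise ValueError("cannot save an unfitted estimator")
    arrays = {"format_version": np.array(MODEL_FORMAT_VERSION)}
    for tag, model in (("ann1", estimator.ann1_), ("ann2", estimator.ann2_)):
        for i in range(3):
            arrays[f"{tag}_w{i}"] = model.coefs_[i]
            arrays[f"{tag}_b{i}"] = model.intercepts_[i]
        arrays.update(_scaler_arrays(f"{tag}_in", model.input_scaler_))
        arrays.update(_scaler_arrays(f"{tag}_out", model.output_scaler_))
        arrays[f"{tag}_loss_history"] = model.loss_history_
        arrays[f"{tag}_grad_history"] = model.grad_history_
        arrays[f"{tag}_params"] = np.array(json.dumps(model.get_params()))
        arrays[f"{tag}_stop"] = np.array([model.stop_reason_, str(model.n_iter_)])
    arrays["metadata"] = np.array(json.dumps(estimator.metadata_))
    arrays["estimator_params"] = np.array(
        json.dumps(
            {
                "scheme": estimator.scheme,
                "feature_set": estimator.feature_set,
                "ann2_train_on": estimator.ann2_train_on,
                "max_train_samples": estimator.max_train_samples,
            }
        )
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_estimator(path) -> ConcatenatedEstimator:
    """Load a saved estimator; predictions match the original bit-exactly."""
    try:
        with np.load(path, allow_pickle=False) as archive:
            if "format_version" not in archive:
                raise ValueError("not an imu2grf model file")
            version = str(archive["format_version"])
            if version != MODEL_FORMAT_VERSION:
                raise ValueError(
                    f"model format {version!r} != expected {MODEL_FORMAT_VERSION!r}"
                )
            est_params = json.loads(str(archive["estimator_params"]))
            est = ConcatenatedEstimator(**est_params)
            for tag in ("ann1", "ann2"):
                params = json.loads(str(archive[f"{tag}_params"]))
                params["hidden_sizes"] = tuple(params["hidden_sizes"])
                model = FeedforwardRegressor(**params)
                model.coefs_ = [archive[f"{tag}_w{i}"] for i in range(3)]
                model.intercepts_ = [archive[f"{tag}_b{i}"] for i in range(3)]
                model.input_scaler_ = _scaler_from(archive, f"{tag}_in")
                model.output_scaler_ = _scaler_from(archive, f"{tag}_out")
                model.loss_history_ = archive[f"{tag}_loss_history"]
                model.grad_history_ = archive[f"{tag}_grad_history"]
                stop = archive[f"{tag}_stop"]
                model.stop_reason_ = str(stop[0])
                model.n_iter_ = int(stop[1])
                model.n_features_in_ = model.coefs_[0].shape[0]
                model.n_outputs_ = model.coefs_[2].shape[1]
                setattr(est, f"{tag}_", model)
            est.metadata_ = json.loads(str(archive["metadata"]))
        return est
    except (ValueError, KeyError) as exc:
        if isinstance(exc, ValueError) and "model" in str(exc):
            raise
        raise ValueError(f"corrupt or truncated model file: {exc}") from exc
    except Exception as exc:  # zipfile/BadZipFile and friends
        raise ValueError(f"corrupt or truncated model file: {exc}") from exc
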