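"""Shallow feedforward fatigue predictor (10-8-1 by default).

A from-scratch single-hidden-layer regression network mapping the ten
HR/HRV features to the composite fatigue index F:

    y = W2 . tanh(W1 x + b1) + b2

Inputs and the target are rescaled feature-wise onto [-1, 1] from the
training split (and predictions mapped back).  Training is full-batch
gradient descent with momentum on the mean squared error of the scaled
target, with backtracking (the step and velocity are halved and retried
whenever a step would increase the loss, so the recorded loss history
is monotone non-increasing) and a mild adaptive rate (grown 5% after
each accepted epoch, capped).  A Levenberg-Marquardt optimizer is
available via ``TrainConfig(optimizer="lm")``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "ScaleParams",
    "MLPParams",
    "TrainConfig",
    "EvalReport",
    "scale_fit",
    "scale_apply",
    "scale_invert",
    "forward",
    "gradients",
    "train",
    "predict",
    "evaluate",
    "crossvalidate",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------- scaling


@dataclass(frozen=True)
class ScaleParams:
    """Per-feature linear map min -> -1, max -> +1 (constant feature -> 0)."""

    lo: np.ndarray
    hi: np.ndarray


def scale_fit(x: np.ndarray) -> ScaleParams:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("scaling requires at least 2 samples")
    return ScaleParams(lo=x.min(axis=0), hi=x.max(axis=0))


def scale_apply(params: ScaleParams, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    span = params.hi - params.lo
    out = np.zeros_like(x, dtype=float)
    varying = span > 0
    out[..., varying] = (
        2.0 * (x[..., varying] - params.lo[varying]) / span[varying] - 1.0
    )
    return out


def scale_invert(params: ScaleParams, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    span = params.hi - params.lo
    out = np.broadcast_to(params.lo, y.shape).copy()
    varying = span > 0
    out[..., varying] = (y[..., varying] + 1.0) / 2.0 * span[varying] + params.lo[
        varying
    ]
    return out


# ------------------------------------------------------------- the network


@dataclass
class MLPParams:
    """Weights, biases and the scaling fitted on the training split."""

    W1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (1, hidden)
    b2: float
    x_scale: ScaleParams | None = None
    y_scale: ScaleParams | None = None
    init_seed: int | None = None


@dataclass(frozen=True)
class TrainConfig:
    """Training regime: defaults follow the reference study settings."""

    learning_rate: float = 0.01
    max_epochs: int = 1000
    goal_mse: float = 1e-5
    hidden_nodes: int = 8
    train_ratio: int = 19  # train : test split ratio, 19:2 on 42 samples
    test_ratio: int = 2
    optimizer: str = "gd"  # "gd" (default) or "lm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.goal_mse <= 0:
            raise ValueError("goal_mse must be > 0")
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")
        if self.optimizer not in ("gd", "lm"):
            raise ValueError("optimizer must be 'gd' or 'lm'")

    def split_sizes(self, n: int) -> tuple[int, int]:
        """Train/test counts for n samples at the configured ratio."""
        n_test = max(1, round(n * self.test_ratio / (self.train_ratio + self.test_ratio)))
        return n - n_test, n_test


def forward(params: MLPParams, x: np.ndarray) -> np.ndarray:
    """Network output for already-scaled input(s); shape (n,) or scalar."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.W1.shape[1]:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects {params.W1.shape[1]}"
        )
    H = np.tanh(X @ params.W1.T + params.b1)
    y = H @ params.W2.ravel() + params.b2
    return float(y[0]) if single else y


def gradients(
    params: MLPParams, X: np.ndarray, y: np.ndarray
) -> tuple[dict[str, np.ndarray], float]:
    """Analytic gradient of the batch MSE w.r.t. every parameter."""
    n = X.shape[0]
    Z = X @ params.W1.T + params.b1
    H = np.tanh(Z)
    yhat = H @ params.W2.ravel() + params.b2
    err = yhat - y
    loss = float(np.mean(err**2))
    dy = 2.0 * err / n  # (n,)
    dW2 = (dy @ H)[None, :]
    db2 = float(dy.sum())
    dH = np.outer(dy, params.W2.ravel())
    dZ = dH * (1.0 - H**2)
    dW1 = dZ.T @ X
    db1 = dZ.sum(axis=0)
    return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}, loss


def _init_params(n_in: int, hidden: int, rng: np.random.Generator) -> MLPParams:
    return MLPParams(
        W1=rng.uniform(-0.5, 0.5, size=(hidden, n_in)),
        b1=rng.uniform(-0.5, 0.5, size=hidden),
        W2=rng.uniform(-0.5, 0.5, size=(1, hidden)),
        b2=float(rng.uniform(-0.5, 0.5)),
    )


def _loss(params: MLPParams, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((forward(params, X) - y) ** 2))


MOMENTUM = 0.9
LR_GROWTH = 1.05
LR_CAP = 100.0  # multiple of the base learning rate


def _train_gd(
    params: MLPParams, X: np.ndarray, y: np.ndarray, config: TrainConfig
) -> list[float]:
    """Full-batch gradient descent with momentum, backtracking, adaptive rate.

    Any step that would increase the loss is halved (velocity damped
    alongside) and retried, so the recorded history is monotone
    non-increasing; after an accepted epoch the rate grows 5%, capped.
    """
    lr = config.learning_rate
    max_lr = LR_CAP * config.learning_rate
    vel: dict[str, np.ndarray | float] = {k: 0.0 for k in ("W1", "b1", "W2", "b2")}
    history: list[float] = []
    loss = _loss(params, X, y)
    for _ in range(config.max_epochs):
        grads, loss = gradients(params, X, y)
        if loss > 1e6:
            raise RuntimeError(
                "training diverged (MSE > 1e6); try a smaller learning rate"
            )
        step = lr
        damped = dict(vel)
        for _retry in range(40):
            v = {k: MOMENTUM * damped[k] - step * grads[k] for k in vel}
            cand = MLPParams(
                W1=params.W1 + v["W1"],
                b1=params.b1 + v["b1"],
                W2=params.W2 + v["W2"],
                b2=params.b2 + float(v["b2"]),
            )
            cand_loss = _loss(cand, X, y)
            if cand_loss <= loss:
                break
            step *= 0.5
            damped = {k: 0.5 * damped[k] for k in damped}
        if cand_loss <= loss:
            params.W1, params.b1 = cand.W1, cand.b1
            params.W2, params.b2 = cand.W2, cand.b2
            vel = v
            loss = cand_loss
            lr = min(step * LR_GROWTH, max_lr)
        else:  # stuck: reset the rate and kill the momentum
            lr = config.learning_rate
            vel = {k: 0.0 for k in vel}
        history.append(loss)
        if loss <= config.goal_mse:
            break
    return history


def _pack(params: MLPParams) -> np.ndarray:
    return np.concatenate(
        [params.W1.ravel(), params.b1, params.W2.ravel(), [params.b2]]
    )


def _unpack(theta: np.ndarray, n_in: int, hidden: int) -> MLPParams:
    i = hidden * n_in
    W1 = theta[:i].reshape(hidden, n_in)
    b1 = theta[i : i + hidden]
    W2 = theta[i + hidden : i + 2 * hidden].reshape(1, hidden)
    b2 = float(theta[i + 2 * hidden])
    return MLPParams(W1=W1, b1=b1, W2=W2, b2=b2)


def _jacobian(params: MLPParams, X: np.ndarray) -> np.ndarray:
    """d yhat_i / d theta: (n, n_params), analytic."""
    n, n_in = X.shape
    hidden = params.b1.size
    H = np.tanh(X @ params.W1.T + params.b1)
    dH = 1.0 - H**2
    w2 = params.W2.ravel()
    dW1 = (dH * w2)[:, :, None] * X[:, None, :]  # (n, hidden, n_in)
    db1 = dH * w2  # (n, hidden)
    dW2 = H  # (n, hidden)
    db2 = np.ones((n, 1))
    return np.concatenate([dW1.reshape(n, -1), db1, dW2, db2], axis=1)


def _train_lm(
    params: MLPParams, X: np.ndarray, y: np.ndarray, config: TrainConfig
) -> list[float]:
    mu, mu_up, mu_down = 1e-3, 10.0, 0.1
    n_in, hidden = X.shape[1], params.b1.size
    theta = _pack(params)
    history: list[float] = []
    for _ in range(config.max_epochs):
        p = _unpack(theta, n_in, hidden)
        r = forward(p, X) - y
        loss = float(np.mean(r**2))
        J = _jacobian(p, X)
        A = J.T @ J
        g = J.T @ r
        accepted = False
        for _retry in range(30):
            try:
                delta = np.linalg.solve(A + mu * np.eye(A.shape[0]), g)
            except np.linalg.LinAlgError:
                mu *= mu_up
                continue
            cand = theta - delta
            cand_loss = float(
                np.mean((forward(_unpack(cand, n_in, hidden), X) - y) ** 2)
            )
            if cand_loss <= loss:
                theta = cand
                loss = cand_loss
                mu = max(mu * mu_down, 1e-12)
                accepted = True
                break
            mu *= mu_up
        history.append(loss)
        if loss <= config.goal_mse or not accepted:
            break
    final = _unpack(theta, n_in, hidden)
    params.W1, params.b1, params.W2, params.b2 = (
        final.W1,
        final.b1,
        final.W2,
        final.b2,
    )
    return history


def train(
    features: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> tuple[MLPParams, list[float]]:
    """Fit the network; returns the parameters and the per-epoch MSE history.

    *features* is (n, n_in) raw (unscaled) input, *targets* the fatigue
    index in [0, 1].  Scaling is fitted on this data (callers pass the
    training split only).  The history is recorded on the scaled target
    and is monotone non-increasing; ``goal_mse`` stops training early.
    """
    X_raw = np.asarray(features, dtype=float)
    y_raw = np.asarray(targets, dtype=float)
    if X_raw.ndim != 2 or y_raw.ndim != 1 or X_raw.shape[0] != y_raw.size:
        raise ValueError("features must be (n, d) and targets (n,)")
    if X_raw.shape[0] < config.hidden_nodes:
        raise ValueError("need at least as many samples as hidden nodes")

    x_scale = scale_fit(X_raw)
    y_scale = scale_fit(y_raw[:, None])
    X = scale_apply(x_scale, X_raw)
    y = scale_apply(y_scale, y_raw[:, None]).ravel()

    rng = np.random.default_rng(config.seed)
    params = _init_params(X.shape[1], config.hidden_nodes, rng)
    params.init_seed = config.seed

    if config.optimizer == "lm":
        history = _train_lm(params, X, y, config)
    else:
        history = _train_gd(params, X, y, config)

    params.x_scale = x_scale
    params.y_scale = y_scale
    return params, history


def predict(params: MLPParams, features: np.ndarray) -> np.ndarray:
    """Fatigue-index predictions on the original [0, 1] scale."""
    if params.x_scale is None or params.y_scale is None:
        raise ValueError("model has no fitted scaling; train it first")
    X = scale_apply(params.x_scale, np.atleast_2d(np.asarray(features, dtype=float)))
    y = forward(params, X)
    return scale_invert(params.y_scale, np.atleast_1d(y)[:, None]).ravel()


# ------------------------------------------------------------- evaluation


@dataclass
class EvalReport:
    """MAE / MSE / RMSE / R^2, optionally with per-fold detail."""

    mae: float
    mse: float
    rmse: float
    r2: float
    folds: list["EvalReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"mae": self.mae, "mse": self.mse, "rmse": self.rmse, "r2": self.r2}
        if self.folds:
            d["folds"] = [f.to_dict() for f in self.folds]
        return d


def evaluate(predictions: np.ndarray, observations: np.ndarray) -> EvalReport:
    """Standard regression metrics; R^2 is NaN for zero-variance observations."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape or p.size < 2:
        raise ValueError("predictions and observations must match, length >= 2")
    err = p - o
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = math.sqrt(mse)
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    r2 = math.nan if ss_tot == 0 else 1.0 - float(np.sum(err**2)) / ss_tot
    return EvalReport(mae=mae, mse=mse, rmse=rmse, r2=r2)


def crossvalidate(
    features: np.ndarray,
    targets: np.ndarray,
    folds: int = 5,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> tuple[EvalReport, np.ndarray]:
    """Seeded k-fold cross-validation.

    Each fold's model is trained (with scaling fitted on its own
    training part) and evaluated on the held-out part.  Returns a report
    whose headline metrics are computed on the pooled out-of-fold
    predictions (42 held-out points on the default cohort) with the
    per-fold reports attached, plus the pooled prediction vector aligned
    with the input order.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    n = y.size
    if folds > n:
        raise ValueError(f"folds={folds} exceeds the {n} available samples")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = np.empty(n)
    fold_reports: list[EvalReport] = []
    for train_idx, test_idx in kf.split(X):
        params, _ = train(X[train_idx], y[train_idx], config)
        pred = predict(params, X[test_idx])
        pooled[test_idx] = pred
        if test_idx.size >= 2:
            fold_reports.append(evaluate(pred, y[test_idx]))
        else:  # leave-one-out fold: r2 undefined on a single point
            err = float(abs(pred[0] - y[test_idx][0]))
            fold_reports.append(
                EvalReport(mae=err, mse=err**2, rmse=err, r2=math.nan)
            )
    report = evaluate(pooled, y)
    report.folds = fold_reports
    return report, pooled


# ------------------------------------------------------------ persistence


def save_model(params: MLPParams, path: str | Path) -> None:
    obj = {
        "W1": params.W1.tolist(),
        "b1": params.b1.tolist(),
        "W2": params.W2.tolist(),
        "b2": params.b2,
        "x_scale": None
        if params.x_scale is None
        else {"lo": params.x_scale.lo.tolist(), "hi": params.x_scale.hi.tolist()},
        "y_scale": None
        if params.y_scale is None
        else {"lo": params.y_scale.lo.tolist(), "hi": params.y_scale.hi.tolist()},
        "init_seed": params.init_seed,
    }
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_model(path: str | Path) -> MLPParams:
    obj = json.loads(Path(path).read_text())

    def _scale(d):
        return None if d is None else ScaleParams(
            lo=np.array(d["lo"]), hi=np.array(d["hi"])
        )

    return MLPParams(
        W1=np.array(obj["W1"]),
        b1=np.array(obj["b1"]),
        W2=np.array(obj["W2"]),
        b2=float(obj["b2"]),
        x_scale=_scale(obj["x_scale"]),
        y_scale=_scale(obj["y_scale"]),
        init_seed=obj.get("init_seed"),
    )
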