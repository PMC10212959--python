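"""Neural vital-capacity estimator.

A three-layer perceptron (identity input layer, tanh hidden layer of H
units, identity output unit) mapping two features — [CPS, VC_LMS] or
[SPL, VC_LMS] — to estimated vital capacity. The model carries exactly
4H + 1 weight and bias parameters. Training minimizes the root mean
squared error; hyperparameter H is selected per outer fold by a nested
(leave-one-out outer, 2-fold inner) cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "MLPModel",
    "TrainConfig",
    "NestedCVResult",
    "init_mlp",
    "predict",
    "train_mlp",
    "nested_cv",
]

FEATURE_SETS = ("CPS+VC_LMS", "SPL+VC_LMS")
N_FEATURES = 2


@dataclass(frozen=True)
class MLPModel:
    """2-input, H-hidden-unit (tanh), 1-output (identity) perceptron."""

    hidden_units: int
    input_weights: np.ndarray  # (H, 2)
    hidden_biases: np.ndarray  # (H,)
    output_weights: np.ndarray  # (H,)
    output_bias: float
    feature_set: str = "CPS+VC_LMS"
    input_center: np.ndarray | None = None  # (2,)
    input_scale: np.ndarray | None = None  # (2,)

    def __post_init__(self) -> None:
        H = self.hidden_units
        if H < 1:
            raise ValueError("hidden_units must be >= 1")
        object.__setattr__(
            self, "input_weights", np.asarray(self.input_weights, dtype=float).reshape(H, N_FEATURES)
        )
        object.__setattr__(
            self, "hidden_biases", np.asarray(self.hidden_biases, dtype=float).reshape(H)
        )
        object.__setattr__(
            self, "output_weights", np.asarray(self.output_weights, dtype=float).reshape(H)
        )

    @property
    def n_parameters(self) -> int:
        """4H + 1."""
        return self.input_weights.size + self.hidden_biases.size + self.output_weights.size + 1

    @property
    def is_scaled(self) -> bool:
        return self.input_center is not None and self.input_scale is not None


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings; the defaults are documented package choices, not
    study values (the study's software defaults are unpublished)."""

    max_epochs: int = 5000
    grad_tol: float = 1e-6
    n_restarts: int = 3
    method: str = "lbfgs"  # "lbfgs" | "gd" (full-batch, adaptive step)
    learning_rate: float = 0.05  # gd only


def init_mlp(H: int, seed: int, feature_set: str = "CPS+VC_LMS") -> MLPModel:
    """Seeded symmetric fan-in-scaled initialization; 4H + 1 parameters."""
    if H < 1:
        raise ValueError("H must be >= 1")
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    rng = np.random.default_rng(seed)
    w_in = rng.uniform(-1, 1, size=(H, N_FEATURES)) / np.sqrt(N_FEATURES)
    b_h = rng.uniform(-1, 1, size=H) / np.sqrt(N_FEATURES)
    w_out = rng.uniform(-1, 1, size=H) / np.sqrt(H)
    return MLPModel(
        hidden_units=H,
        input_weights=w_in,
        hidden_biases=b_h,
        output_weights=w_out,
        output_bias=0.0,
        feature_set=feature_set,
    )


def predict(model: MLPModel, features: np.ndarray) -> np.ndarray:
    """Forward pass on (n, 2) or (2,) features; requires fitted scaling."""
    if not model.is_scaled:
        raise ValueError("model input scaling not fitted; train first")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    z = (X - model.input_center) / model.input_scale
    hidden = np.tanh(z @ model.input_weights.T + model.hidden_biases)
    out = hidden @ model.output_weights + model.output_bias
    return out if np.asarray(features).ndim > 1 else float(out[0])


def _pack(model: MLPModel) -> np.ndarray:
    return np.concatenate(
        [
            model.input_weights.ravel(),
            model.hidden_biases,
            model.output_weights,
            [model.output_bias],
        ]
    )


def _unpack(theta: np.ndarray, H: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    k = H * N_FEATURES
    return (
        theta[:k].reshape(H, N_FEATURES),
        theta[k : k + H],
        theta[k + H : k + 2 * H],
        float(theta[k + 2 * H]),
    )


def _loss_grad(theta: np.ndarray, H: int, Z: np.ndarray, y: np.ndarray):
    W, b, v, c = _unpack(theta, H)
    a = Z @ W.T + b
    h = np.tanh(a)
    yhat = h @ v + c
    resid = yhat - y
    n = y.size
    loss = float(resid @ resid) / n
    r = (2.0 / n) * resid
    dv = h.T @ r
    dc = r.sum()
    da = np.outer(r, v) * (1.0 - h * h)
    dW = da.T @ Z
    db = da.sum(axis=0)
    return loss, np.concatenate([dW.ravel(), db, dv, [dc]])


def _fit_scaling(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return center, scale


def _minimize_gd(theta0, H, Z, y, cfg: TrainConfig):
    # Full-batch gradient descent with adaptive step: halve on loss increase,
    # grow mildly on acceptance. Reference implementation; slower than lbfgs.
    theta = theta0.copy()
    lr = cfg.learning_rate
    loss, grad = _loss_grad(theta, H, Z, y)
    for _ in range(cfg.max_epochs):
        if np.linalg.norm(grad) < cfg.grad_tol:
            break
        trial = theta - lr * grad
        trial_loss, trial_grad = _loss_grad(trial, H, Z, y)
        if not np.isfinite(trial_loss):
            raise FloatingPointError("non-finite training loss")
        if trial_loss <= loss:
            theta, loss, grad = trial, trial_loss, trial_grad
            lr *= 1.1
        else:
            lr *= 0.5
    return theta, loss


def train_mlp(
    model: MLPModel,
    X: np.ndarray,
    y: np.ndarray,
    hyper: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> MLPModel:
    """Train on (n, 2) features and measured VC targets.

    Input standardization (center/scale) is fitted on the training data
    only. ``n_restarts`` seeded random re-initializations are run and the
    lowest final loss kept; deterministic given (data, hyper, seed).
    """
    X = np.asarray(X, dtype=float).reshape(-1, N_FEATURES)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    if np.any(y <= 0):
        raise ValueError("measured VC targets must be positive")
    H = model.hidden_units
    if y.size < model.n_parameters:
        import warnings

        warnings.warn(
            f"fewer observations ({y.size}) than parameters ({model.n_parameters})",
            stacklevel=2,
        )
    center, scale = _fit_scaling(X)
    Z = (X - center) / scale

    starts = [_pack(model)]
    seeds = np.random.SeedSequence([seed, 0xC0FFEE]).generate_state(max(hyper.n_restarts - 1, 0))
    starts += [
        _pack(init_mlp(H, int(s), model.feature_set)) for s in seeds
    ]
    # anchor output bias at the target mean so a constant fit is in reach
    for theta in starts:
        theta[-1] = y.mean()

    best_theta, best_loss = None, np.inf
    for theta0 in starts:
        if hyper.method == "gd":
            theta, loss = _minimize_gd(theta0, H, Z, y, hyper)
        else:
            res = minimize(
                _loss_grad,
                theta0,
                args=(H, Z, y),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": hyper.max_epochs, "gtol": hyper.grad_tol},
            )
            theta, loss = res.x, float(res.fun)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        if loss < best_loss:
            best_theta, best_loss = theta, loss

    W, b, v, c = _unpack(best_theta, H)
    return replace(
        model,
        input_weights=W,
        hidden_biases=b,
        output_weights=v,
        output_bias=c,
        input_center=center,
        input_scale=scale,
    )


@dataclass(frozen=True)
class NestedCVResult:
    """Leave-one-out nested cross-validation output: one prediction per
    observation, each produced by a model never trained on it."""

    predictions: np.ndarray  # (N,)
    chosen_H: np.ndarray  # (N,)
    inner_rmse: np.ndarray  # (N, len(H_grid)); mean over inner orientations
    H_grid: tuple[int, ...]
    overall_rmse: float
    feature_set: str = "CPS+VC_LMS"


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    H_grid: tuple[int, ...] = (1, 2, 3),
    seed: int = 0,
    hyper: TrainConfig = TrainConfig(),
    feature_set: str = "CPS+VC_LMS",
) -> NestedCVResult:
    """Leave-one-out outer loop; per fold the N-1 training rows are shuffled
    into two halves (sizes ceil/floor for odd counts) and both orientations
    train-on-one-half / evaluate-on-the-other are scored; the H with the
    lowest mean inner RMSE (ties to the smallest H) is refit on all N-1 rows
    to predict the held-out observation.
    """
    X = np.asarray(X, dtype=float).reshape(-1, N_FEATURES)
    y = np.asarray(y, dtype=float).ravel()
    N = y.size
    if N < 8:
        raise ValueError("nested CV requires N >= 8")
    H_grid = tuple(sorted(H_grid))
    predictions = np.empty(N)
    chosen = np.empty(N, dtype=int)
    inner_tbl = np.empty((N, len(H_grid)))

    for i in range(N):
        train_idx = np.delete(np.arange(N), i)
        # fold seeds derive from (seed, i) only - never from the data
        fold_ss = np.random.SeedSequence([seed, i])
        shuffle_seed, *model_seeds = fold_ss.generate_state(2 + len(H_grid))
        rng = np.random.default_rng(shuffle_seed)
        perm = rng.permutation(train_idx)
        n_half = int(np.ceil(perm.size / 2))
        halves = (perm[:n_half], perm[n_half:])

        for j, H in enumerate(H_grid):
            scores = []
            for fit_half, eval_half in (halves, halves[::-1]):
                m0 = init_mlp(H, int(model_seeds[j]), feature_set)
                m = train_mlp(m0, X[fit_half], y[fit_half], hyper, seed=int(model_seeds[j]))
                scores.append(_rmse(predict(m, X[eval_half]), y[eval_half]))
            inner_tbl[i, j] = float(np.mean(scores))
        best_j = int(np.argmin(inner_tbl[i]))  # argmin -> smallest H on ties
        chosen[i] = H_grid[best_j]

        m0 = init_mlp(chosen[i], int(model_seeds[-1]), feature_set)
        final = train_mlp(m0, X[train_idx], y[train_idx], hyper, seed=int(model_seeds[-1]))
        predictions[i] = predict(final, X[i])

    return NestedCVResult(
        predictions=predictions,
        chosen_H=chosen,
        inner_rmse=inner_tbl,
        H_grid=H_grid,
        overall_rmse=_rmse(predictions, y),
        feature_set=feature_set,
    )
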