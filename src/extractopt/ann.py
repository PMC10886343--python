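"""Small feed-forward MLP regressor used as a nonlinear surrogate model.

A single tanh hidden layer with a linear output unit, trained on min-max
scaled inputs/outputs (to [-1, 1]) by either Levenberg-Marquardt or BFGS,
with a seeded train/validation/test split and validation-based early
stopping.  This is the classical small-data "RSM vs ANN" setup: one network
per response, a handful of hidden units, weights kept at the epoch with the
best validation MSE.

The network with ``h`` hidden units computes

    f(x) = w2 . tanh(W1 x + b1) + b2        (+ w_skip . x  if cascade)

and training minimizes the mean squared error on the training subset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DivergenceError, SplitError


def split_sizes(n: int, fractions=(0.70, 0.15, 0.15)) -> tuple[int, int, int]:
    """Partition sizes: train rounded, validation floored, remainder to test."""
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise SplitError("split fractions must sum to 1")
    n_train = int(math.floor(f_train * n + 0.5))
    n_val = int(math.floor(f_val * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise SplitError(f"empty partition for n={n}, fractions={fractions}")
    return n_train, n_val, n_test


def split_data(n: int, fractions=(0.70, 0.15, 0.15), seed: int = 0):
    """Seeded shuffle split into disjoint, exhaustive train/val/test indices."""
    n_train, n_val, n_test = split_sizes(n, fractions)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return (
        np.sort(perm[:n_train]),
        np.sort(perm[n_train : n_train + n_val]),
        np.sort(perm[n_train + n_val :]),
    )


def _unpack(params, n_in, hidden, cascade):
    """Flat parameter vector -> (W1, b1, w2, b2, w_skip)."""
    i = 0
    W1 = params[i : i + hidden * n_in].reshape(hidden, n_in); i += hidden * n_in
    b1 = params[i : i + hidden]; i += hidden
    w2 = params[i : i + hidden]; i += hidden
    b2 = params[i]; i += 1
    w_skip = None
    if cascade:
        w_skip = params[i : i + n_in]; i += n_in
    return W1, b1, w2, b2, w_skip


def _n_params(n_in, hidden, cascade):
    return hidden * n_in + hidden + hidden + 1 + (n_in if cascade else 0)


def forward(params, X, hidden, cascade=False):
    """Network output for scaled inputs X (n, d)."""
    n_in = X.shape[1]
    W1, b1, w2, b2, w_skip = _unpack(params, n_in, hidden, cascade)
    A = np.tanh(X @ W1.T + b1)
    out = A @ w2 + b2
    if cascade:
        out = out + X @ w_skip
    return out


def residual_jacobian(params, X, hidden, cascade=False):
    """Jacobian of the per-sample network output w.r.t. the flat parameters."""
    n, n_in = X.shape
    W1, b1, w2, b2, w_skip = _unpack(params, n_in, hidden, cascade)
    Z = X @ W1.T + b1
    A = np.tanh(Z)
    dA = 1.0 - A**2  # (n, h)
    J = np.empty((n, _n_params(n_in, hidden, cascade)))
    # d f / d W1[i, j] = w2[i] * (1 - tanh^2 z_i) * x_j
    JW1 = (dA * w2)[:, :, None] * X[:, None, :]  # (n, h, d)
    i = 0
    J[:, i : i + hidden * n_in] = JW1.reshape(n, -1); i += hidden * n_in
    J[:, i : i + hidden] = dA * w2; i += hidden
    J[:, i : i + hidden] = A; i += hidden
    J[:, i] = 1.0; i += 1
    if cascade:
        J[:, i : i + n_in] = X; i += n_in
    return J


def mse_loss_and_grad(params, X, y, hidden, cascade=False):
    """Training MSE and its analytic gradient (for BFGS and gradient checks)."""
    pred = forward(params, X, hidden, cascade)
    r = pred - y
    J = residual_jacobian(params, X, hidden, cascade)
    n = len(y)
    return float(r @ r) / n, (2.0 / n) * (J.T @ r)


@dataclass
class _History:
    epochs: list
    train_mse: list
    val_mse: list


class MLPSurrogate(RegressorMixin, BaseEstimator):
    """One-hidden-layer tanh MLP with early stopping, sklearn-style.

    Parameters
    ----------
    hidden_units : int, default 5
        Width of the tanh hidden layer.  With ~17 design points, wider
        layers memorize; 5 keeps the parameter count below n.
    trainer : {"levenberg_marquardt", "bfgs"}
        Optimizer.  Levenberg-Marquardt uses adaptive damping (lambda x10
        on a rejected step, /10 on an accepted one).
    fractions : (train, validation, test) split fractions, summing to 1.
    seed : int
        Seeds both the split shuffle and the weight initialization.
    max_epochs : int
    patience : int
        Stop after this many validation checks without improvement.
    cascade : bool
        Add direct input-to-output skip connections.
    """

    def __init__(
        self,
        hidden_units: int = 5,
        trainer: str = "levenberg_marquardt",
        fractions=(0.70, 0.15, 0.15),
        seed: int = 0,
        max_epochs: int = 100,
        patience: int = 6,
        cascade: bool = False,
    ):
        self.hidden_units = hidden_units
        self.trainer = trainer
        self.fractions = fractions
        self.seed = seed
        self.max_epochs = max_epochs
        self.patience = patience
        self.cascade = cascade

    # min-max scaling to [-1, 1]
    def _scale_x(self, X):
        span = np.where(self.x_max_ > self.x_min_, self.x_max_ - self.x_min_, 1.0)
        return 2.0 * (X - self.x_min_) / span - 1.0

    def _scale_y(self, y):
        span = self.y_max_ - self.y_min_ if self.y_max_ > self.y_min_ else 1.0
        return 2.0 * (y - self.y_min_) / span - 1.0

    def _unscale_y(self, ys):
        span = self.y_max_ - self.y_min_ if self.y_max_ > self.y_min_ else 1.0
        return (ys + 1.0) / 2.0 * span + self.y_min_

    def fit(self, X, y):
        if self.trainer not in ("levenberg_marquardt", "bfgs"):
            raise ValueError(f"unknown trainer {self.trainer!r}")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n, d) with matching y")
        n, d = X.shape
        if n < 5:
            raise SplitError("need at least 5 samples to split")

        self.x_min_, self.x_max_ = X.min(axis=0), X.max(axis=0)
        self.y_min_, self.y_max_ = float(y.min()), float(y.max())
        Xs, ys = self._scale_x(X), self._scale_y(y)

        tr, va, te = split_data(n, self.fractions, self.seed)
        self.split_ = {"train": tr, "validation": va, "test": te}

        rng = np.random.default_rng(self.seed)
        # small weights start every tanh unit in its linear regime, so early
        # epochs fit the smooth large-scale structure first
        params = rng.uniform(-0.2, 0.2, _n_params(d, self.hidden_units, self.cascade))

        history = _History([], [], [])
        best_val, best_params, best_epoch = np.inf, params.copy(), 0
        stall = 0
        lam = 1e-2  # LM damping

        def record(epoch, p):
            nonlocal best_val, best_params, best_epoch, stall
            mse_tr = float(np.mean((forward(p, Xs[tr], self.hidden_units, self.cascade) - ys[tr]) ** 2))
            mse_va = float(np.mean((forward(p, Xs[va], self.hidden_units, self.cascade) - ys[va]) ** 2))
            if not (np.isfinite(mse_tr) and np.isfinite(mse_va)):
                raise DivergenceError("non-finite loss during training", history=history)
            history.epochs.append(epoch)
            history.train_mse.append(mse_tr)
            history.val_mse.append(mse_va)
            if mse_va < best_val - 1e-15:
                best_val, best_params, best_epoch = mse_va, p.copy(), epoch
                stall = 0
            else:
                stall += 1
            return stall > self.patience

        record(0, params)
        if self.trainer == "levenberg_marquardt":
            for epoch in range(1, self.max_epochs + 1):
                r = ys[tr] - forward(params, Xs[tr], self.hidden_units, self.cascade)
                sse = float(r @ r)
                J = residual_jacobian(params, Xs[tr], self.hidden_units, self.cascade)
                JTJ, JTr = J.T @ J, J.T @ r
                # Marquardt's diagonal scaling: damp relative to each
                # parameter's own curvature, not isotropically
                D = np.diag(np.diag(JTJ)) + 1e-12 * np.eye(len(params))
                accepted = False
                for _ in range(25):
                    try:
                        step = np.linalg.solve(JTJ + lam * D, JTr)
                    except np.linalg.LinAlgError:
                        lam *= 10.0
                        continue
                    cand = params + step
                    r_new = ys[tr] - forward(cand, Xs[tr], self.hidden_units, self.cascade)
                    if float(r_new @ r_new) < sse:
                        params, lam, accepted = cand, max(lam / 10.0, 1e-12), True
                        break
                    lam *= 10.0
                if not accepted:
                    break  # converged: no damped step improves the fit
                if record(epoch, params):
                    break
        else:  # bfgs
            from scipy import optimize

            state = {"epoch": 0, "stop": False}

            def cb(xk):
                state["epoch"] += 1
                if record(state["epoch"], xk):
                    state["stop"] = True
                    raise StopIteration

            try:
                optimize.minimize(
                    mse_loss_and_grad,
                    params,
                    args=(Xs[tr], ys[tr], self.hidden_units, self.cascade),
                    jac=True,
                    method="BFGS",
                    callback=cb,
                    options={"maxiter": self.max_epochs, "gtol": 1e-12},
                )
            except StopIteration:
                pass

        self.params_ = best_params
        self.best_epoch_ = best_epoch
        self.stopping_epoch_ = history.epochs[-1]
        self.history_ = {
            "epoch": history.epochs,
            "train_mse": history.train_mse,
            "val_mse": history.val_mse,
        }
        self.n_features_in_ = d
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        out = forward(self.params_, self._scale_x(X), self.hidden_units, self.cascade)
        return self._unscale_y(out)

    def to_json(self) -> str:
        check_is_fitted(self, "params_")
        return json.dumps(
            {
                "config": self.get_params(),
                "params": self.params_.tolist(),
                "scaling": {
                    "x_min": self.x_min_.tolist(),
                    "x_max": self.x_max_.tolist(),
                    "y_min": self.y_min_,
                    "y_max": self.y_max_,
                },
                "history": self.history_,
                "best_epoch": self.best_epoch_,
                "stopping_epoch": self.stopping_epoch_,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MLPSurrogate":
        payload = json.loads(text)
        cfg = payload["config"]
        cfg["fractions"] = tuple(cfg["fractions"])
        model = cls(**cfg)
        model.params_ = np.array(payload["params"])
        sc = payload["scaling"]
        model.x_min_ = np.array(sc["x_min"])
        model.x_max_ = np.array(sc["x_max"])
        model.y_min_, model.y_max_ = sc["y_min"], sc["y_max"]
        model.history_ = payload["history"]
        model.best_epoch_ = payload["best_epoch"]
        model.stopping_epoch_ = payload["stopping_epoch"]
        model.n_features_in_ = len(sc["x_min"])
        return model


def best_of_seeds(X, y, seeds, **kwargs) -> MLPSurrogate:
    """Train one surrogate per seed and keep the best overall-R^2 network."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    sst = float(np.sum((y - y.mean()) ** 2))
    best, best_r2 = None, -np.inf
    for seed in seeds:
        model = MLPSurrogate(seed=seed, **kwargs).fit(X, y)
        sse = float(np.sum((y - model.predict(X)) ** 2))
        r2 = 1 - sse / sst
        if r2 > best_r2:
            best, best_r2 = model, r2
    return best
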