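"""A small fully-connected regressor trained with Adam on MAE loss.

Architecture and training recipe used by the nonlinear autoregressive
metric: one hidden layer (144 → 32 → 1) with ReLU, Adam (lr 0.001),
mean-absolute-error loss with an L1 weight penalty (λ = 1e-5, weights only),
50 epochs, and best-epoch selection on a validation split monitored by R².
Implemented directly on numpy; weights start from a fixed-seed uniform
fan-in scheme, and mini-batch order is reshuffled deterministically each
epoch, so training is bit-reproducible for a given random_state.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import r2_score


class MLPRegressorNumpy(BaseEstimator, RegressorMixin):
    """Single-hidden-layer ReLU network for time-series regression.

    Parameters mirror the analysis defaults: ``hidden=32``, ``epochs=50``,
    ``lr=1e-3``, ``l1=1e-5`` (applied to weights, not biases),
    ``batch_size=128``.  When ``fit`` receives ``validation_data``, the
    per-epoch validation R² path is recorded and the parameters from the
    best epoch are restored (``best_epoch_``, 1-based).
    """

    def __init__(self, hidden: int = 32, epochs: int = 50, lr: float = 1e-3,
                 l1: float = 1e-5, batch_size: int = 128,
                 random_state: int | None = 0):
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.l1 = l1
        self.batch_size = batch_size
        self.random_state = random_state

    # -- internals ----------------------------------------------------------
    def _init_params(self, n_features: int, rng: np.random.Generator):
        # uniform fan-in initialisation: U(-1/sqrt(fan_in), 1/sqrt(fan_in))
        b1 = 1.0 / np.sqrt(n_features)
        b2 = 1.0 / np.sqrt(self.hidden)
        return {
            "W1": rng.uniform(-b1, b1, size=(n_features, self.hidden)),
            "b1": rng.uniform(-b1, b1, size=self.hidden),
            "W2": rng.uniform(-b2, b2, size=(self.hidden, 1)),
            "b2": rng.uniform(-b2, b2, size=1),
        }

    @staticmethod
    def _forward(params, X):
        z1 = X @ params["W1"] + params["b1"]
        h = np.maximum(z1, 0.0)
        out = (h @ params["W2"] + params["b2"]).reshape(-1)
        return z1, h, out

    def _grads(self, params, X, y):
        n = len(y)
        z1, h, out = self._forward(params, X)
        # MAE loss: dL/dout = sign(out - y)/n
        g_out = np.sign(out - y)[:, None] / n
        gW2 = h.T @ g_out + self.l1 * np.sign(params["W2"])
        gb2 = g_out.sum(axis=0)
        g_h = g_out @ params["W2"].T
        g_z1 = g_h * (z1 > 0)
        gW1 = X.T @ g_z1 + self.l1 * np.sign(params["W1"])
        gb1 = g_z1.sum(axis=0)
        return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}

    # -- API ----------------------------------------------------------------
    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per target")
        rng = np.random.default_rng(self.random_state)
        params = self._init_params(X.shape[1], rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v_adam = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.val_r2_path_ = []
        best = (-np.inf, None)
        n = len(y)
        bs = min(self.batch_size, n)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, bs):
                idx = order[lo:lo + bs]
                grads = self._grads(params, X[idx], y[idx])
                step += 1
                for k in params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1 ** step)
                    vhat = v_adam[k] / (1 - beta2 ** step)
                    params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)
            if validation_data is not None:
                Xv, yv = validation_data
                _, _, pv = self._forward(params, np.asarray(Xv, dtype=float))
                r2 = r2_score(np.asarray(yv, dtype=float).reshape(-1), pv)
                self.val_r2_path_.append(r2)
                if r2 > best[0]:
                    best = (r2, {k: p.copy() for k, p in params.items()})
        if validation_data is not None and best[1] is not None:
            self.params_ = best[1]
            self.best_epoch_ = int(np.argmax(self.val_r2_path_)) + 1
            self.best_val_r2_ = float(best[0])
        else:
            self.params_ = params
            self.best_epoch_ = self.epochs
            self.best_val_r2_ = float("nan")
        return self

    def predict(self, X):
        _, _, out = self._forward(self.params_, np.asarray(X, dtype=float))
        return out
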