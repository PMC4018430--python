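"""A small feed-forward network trained by full-batch L-BFGS.

One hidden tanh layer, linear output(s), L2 penalty on the weights.
Written for the p >> n regime of microarray modeling: weights start near
zero (symmetric ties broken by a tiny random component), so after
optimization every weight is there because the data demanded it — the
ridge-like minimum concentrates input weight on informative, mutually
correlated inputs instead of leaving random initialization noise behind.
That property is what makes perturbation sensitivities interpretable as
variable importance.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = ["TinyNet"]


class TinyNet:
    """Single-hidden-layer tanh network, deterministic L-BFGS training.

    Parameters
    ----------
    n_hidden : hidden unit count.
    alpha : L2 penalty on all weights (not biases), in units of the
        per-sample squared-error loss.
    seed : seed for the (tiny) symmetry-breaking initialization.
    init_scale : sd of the initial weights; small by design.
    """

    def __init__(self, n_hidden: int = 3, alpha: float = 1e-2, seed: int = 0,
                 max_iter: int = 2000, init_scale: float = 1e-3):
        self.n_hidden = int(n_hidden)
        self.alpha = float(alpha)
        self.seed = int(seed)
        self.max_iter = int(max_iter)
        self.init_scale = float(init_scale)
        self.coef_: tuple | None = None

    # parameter vector layout: W1 (h, p), b1 (h), W2 (k, h), b2 (k)
    def _unpack(self, theta: np.ndarray, p: int, k: int):
        h = self.n_hidden
        i = 0
        W1 = theta[i: i + h * p].reshape(h, p); i += h * p
        b1 = theta[i: i + h]; i += h
        W2 = theta[i: i + k * h].reshape(k, h); i += k * h
        b2 = theta[i: i + k]
        return W1, b1, W2, b2

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "TinyNet":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        k = Y.shape[1]
        h = self.n_hidden
        rng = np.random.default_rng(self.seed)
        theta0 = rng.normal(0.0, self.init_scale, h * p + h + k * h + k)

        def loss_grad(theta):
            W1, b1, W2, b2 = self._unpack(theta, p, k)
            A = X @ W1.T + b1          # (n, h)
            H = np.tanh(A)
            F = H @ W2.T + b2          # (n, k)
            R = F - Y
            loss = 0.5 * (R * R).sum() / n
            loss += 0.5 * self.alpha * ((W1 * W1).sum() + (W2 * W2).sum())
            gF = R / n                 # (n, k)
            gW2 = gF.T @ H + self.alpha * W2
            gb2 = gF.sum(axis=0)
            gH = gF @ W2               # (n, h)
            gA = gH * (1.0 - H * H)
            gW1 = gA.T @ X + self.alpha * W1
            gb1 = gA.sum(axis=0)
            grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
            return loss, grad

        res = minimize(
            loss_grad, theta0, jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": 1e-10, "ftol": 1e-14},
        )
        self.coef_ = self._unpack(res.x, p, k)
        self.n_iter_ = int(res.nit)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("predict before fit")
        W1, b1, W2, b2 = self.coef_
        out = np.tanh(np.asarray(X, dtype=float) @ W1.T + b1) @ W2.T + b2
        return out[:, 0] if out.shape[1] == 1 else out
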