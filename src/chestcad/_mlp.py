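"""Minimal fully connected three-layer networks trained by mini-batch GD.

Two variants share the forward/backward machinery: a linear-output regressor
(the per-level bone-suppression unit) and a sigmoid-output binary classifier
(the baseline candidate classifier).  Plain mini-batch gradient descent with
a fixed learning rate; everything is seeded and deterministic.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class ThreeLayerNet:
    """d -> hidden (sigmoid) -> 1, linear or sigmoid output."""

    def __init__(self, n_inputs: int, n_hidden: int, seed: int, output: str = "linear"):
        if output not in ("linear", "sigmoid"):
            raise ValueError("output must be 'linear' or 'sigmoid'")
        rng = np.random.default_rng(seed)
        s1 = 1.0 / np.sqrt(n_inputs)
        s2 = 1.0 / np.sqrt(n_hidden)
        self.W1 = rng.normal(0.0, s1, size=(n_inputs, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(0.0, s2, size=(n_hidden, 1))
        self.b2 = np.zeros(1)
        self.output = output
        self.seed = seed

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = _sigmoid(X @ self.W1 + self.b1)
        y = (h @ self.W2 + self.b2).ravel()
        return _sigmoid(y) if self.output == "sigmoid" else y

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        lr: float,
        batch_size: int,
        seed: int,
    ) -> float:
        """Minimize MSE (linear) or squared error on probabilities (sigmoid).

        Returns the final full-set mean squared error.  Raises if the loss
        goes non-finite (the caller annotates with its own context).
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        n = X.shape[0]
        rng = np.random.default_rng(seed)
        for epoch in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = X[idx], y[idx]
                h = _sigmoid(xb @ self.W1 + self.b1)
                z = (h @ self.W2 + self.b2).ravel()
                out = _sigmoid(z) if self.output == "sigmoid" else z
                err = out - yb
                if not np.all(np.isfinite(err)):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                m = len(idx)
                dz = 2.0 * err / m
                if self.output == "sigmoid":
                    dz = dz * out * (1.0 - out)
                dW2 = h.T @ dz[:, None]
                db2 = dz.sum(keepdims=True)
                dh = dz[:, None] @ self.W2.T * h * (1.0 - h)
                dW1 = xb.T @ dh
                db1 = dh.sum(axis=0)
                self.W1 -= lr * dW1
                self.b1 -= lr * db1
                self.W2 -= lr * dW2
                self.b2 -= lr * db2
        resid = self.forward(X) - y
        return float(np.mean(resid**2))
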