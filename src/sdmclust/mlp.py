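"""A small feed-forward network for binary cell classification.

Logistic-sigmoid hidden layers, a single linear output unit, and two
trainers: damped Gauss-Newton (Levenberg-Marquardt) on the per-sample
residuals with an analytic Jacobian, and full-batch gradient descent
with momentum.  Training stops once the mean squared error reaches the
termination threshold (default 0.01) or the epoch/iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


@dataclass
class MlpConfig:
    hidden_layers: tuple[int, ...] = (16, 30)
    trainer: str = "levenberg_marquardt"  # or "momentum_sgd"
    learning_rate: float = 0.1
    momentum: float = 0.8
    termination_error: float = 0.01  # mean squared error target
    max_epochs: int = 2000
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden_layers) < 1:
            raise ValueError("need at least one hidden layer")
        if not 0.0 < self.learning_rate < 1.0 or not 0.0 < self.momentum < 1.0:
            raise ValueError("learning rate and momentum must lie in (0, 1)")
        if self.trainer not in ("levenberg_marquardt", "momentum_sgd"):
            raise ValueError(f"unknown trainer {self.trainer!r}")


class MlpModel:
    """Trained network; targets are 0/1, the output unit is linear.

    Hard labels threshold the linear output at 0.5; class probabilities
    pass the output through a logistic link centred on that threshold,
    so the decision boundary maps to probability 0.5.
    """

    def __init__(self, cfg: MlpConfig, n_inputs: int):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        sizes = [n_inputs, *cfg.hidden_layers, 1]
        self.weights = [rng.normal(0.0, 1.0 / np.sqrt(sizes[i]), (sizes[i], sizes[i + 1]))
                        for i in range(len(sizes) - 1)]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.final_mse: float | None = None

    # -- forward / jacobian -------------------------------------------------

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [X]
        a = X
        for li in range(len(self.weights) - 1):
            a = _sigmoid(a @ self.weights[li] + self.biases[li])
            acts.append(a)
        z = (a @ self.weights[-1] + self.biases[-1]).ravel()
        return z, acts

    def _pack(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.weights]
                              + [b.ravel() for b in self.biases])

    def _unpack(self, theta: np.ndarray) -> None:
        pos = 0
        for i, w in enumerate(self.weights):
            self.weights[i] = theta[pos:pos + w.size].reshape(w.shape)
            pos += w.size
        for i, b in enumerate(self.biases):
            self.biases[i] = theta[pos:pos + b.size].reshape(b.shape)
            pos += b.size

    def _jacobian(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """d z / d theta for every sample, via reverse accumulation."""
        z, acts = self._forward(X)
        n = X.shape[0]
        deltas = [None] * len(self.weights)
        # output layer: dz/d(pre-activation) = 1
        delta = np.ones((n, 1))
        deltas[-1] = delta
        for li in range(len(self.weights) - 2, -1, -1):
            a_out = acts[li + 1]
            delta = (delta @ self.weights[li + 1].T) * a_out * (1.0 - a_out)
            deltas[li] = delta
        blocks = []
        for li in range(len(self.weights)):
            # weight grad: a_in[:, :, None] * delta[:, None, :]
            blocks.append((acts[li][:, :, None] * deltas[li][:, None, :]).reshape(n, -1))
        for li in range(len(self.weights)):
            blocks.append(deltas[li])
        return z, np.concatenate(blocks, axis=1)

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MlpModel":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        if self.cfg.trainer == "levenberg_marquardt":
            self._fit_lm(X, y)
        else:
            self._fit_sgd(X, y)
        return self

    def _fit_lm(self, X: np.ndarray, y: np.ndarray, max_iter: int = 200) -> None:
        mu = 1e-2
        theta = self._pack()
        z, J = self._jacobian(X)
        r = y - z
        mse = float(np.mean(r ** 2))
        for _ in range(max_iter):
            if mse <= self.cfg.termination_error:
                break
            A = J.T @ J
            g = J.T @ r
            improved = False
            for _ in range(30):  # adapt damping until the step helps
                try:
                    step = np.linalg.solve(A + mu * np.eye(A.shape[0]), g)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                self._unpack(theta + step)
                z_new, _ = self._forward(X)
                mse_new = float(np.mean((y - z_new) ** 2))
                if mse_new < mse:
                    theta = theta + step
                    mse = mse_new
                    mu = max(mu / 10.0, 1e-12)
                    improved = True
                    break
                mu *= 10.0
                if mu > 1e10:
                    break
            if not improved:
                break
            self._unpack(theta)
            z, J = self._jacobian(X)
            r = y - z
        self._unpack(theta)
        self.final_mse = mse

    def _fit_sgd(self, X: np.ndarray, y: np.ndarray) -> None:
        lr, mom = self.cfg.learning_rate, self.cfg.momentum
        vel_w = [np.zeros_like(w) for w in self.weights]
        vel_b = [np.zeros_like(b) for b in self.biases]
        n = X.shape[0]
        mse = np.inf
        for _ in range(self.cfg.max_epochs):
            z, acts = self._forward(X)
            r = z - y
            mse = float(np.mean(r ** 2))
            if mse <= self.cfg.termination_error:
                break
            # backprop of the MSE gradient
            delta = (2.0 / n) * r[:, None]
            for li in range(len(self.weights) - 1, -1, -1):
                gw = acts[li].T @ delta
                gb = delta.sum(axis=0)
                if li > 0:
                    a_out = acts[li]
                    delta = (delta @ self.weights[li].T) * a_out * (1.0 - a_out)
                vel_w[li] = mom * vel_w[li] - lr * gw
                vel_b[li] = mom * vel_b[li] - lr * gb
                self.weights[li] += vel_w[li]
                self.biases[li] += vel_b[li]
        self.final_mse = mse

    # -- inference ----------------------------------------------------------

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        z, _ = self._forward(np.asarray(X, dtype=np.float64))
        return z

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_values(X) >= 0.5).astype(int)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p1 = _sigmoid(4.0 * (self.decision_values(X) - 0.5))
        return np.column_stack([1.0 - p1, p1])


def train_mlp(X: np.ndarray, y: np.ndarray, cfg: MlpConfig | None = None) -> MlpModel:
    """Train one network on scaled features and 0/1 labels."""
    cfg = cfg or MlpConfig()
    X = np.asarray(X, dtype=np.float64)
    return MlpModel(cfg, X.shape[1]).fit(X, y)
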