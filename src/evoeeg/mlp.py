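"""The MLP event classifier with geometric ("horizontal pyramid") sizing.

The network has two hidden ReLU layers and a single sigmoid output unit
acting as the decision function. Hidden sizes are derived from the input
and output sizes through a proportion factor

    kappa = (IL / OL)^(1/3),   HL1 = round(OL * kappa^2),
                               HL2 = round(OL * kappa),

so layer widths shrink geometrically from input to output. Training
minimises the mean squared error between the sigmoid output and the 0/1
labels by minibatch backpropagation for a fixed number of epochs,
reproducible bit-for-bit from a seed — a requirement of the wrapper
search, whose fitness comparisons are only meaningful when refits are
deterministic. The default optimizer is Adam: with all-positive
min-max-scaled inputs and heavy class imbalance, plain gradient descent
at a rate large enough to learn in 10 epochs collapses the ReLU layers
(all units die and the output goes constant), while Adam's
per-parameter step normalisation trains reliably; plain (momentum) SGD
remains available via ``optimizer="sgd"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MLPError(ValueError):
    pass


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _round(x: float) -> int:
    return int(np.floor(x + 0.5))


def size_layers(IL: int, OL: int = 1, rule: str = "cube_root") -> "MLPSpec":
    """Hidden-layer sizes from input/output sizes via the proportion factor.

    ``rule="cube_root"`` gives the geometric pyramid above;
    ``rule="sqrt"`` uses kappa = sqrt(IL/OL) instead. Results are clamped
    so that IL >= HL1 >= HL2 >= OL after rounding.
    """
    if IL < 1 or OL < 1:
        raise MLPError(f"layer sizes must be >= 1, got IL={IL}, OL={OL}")
    if IL < OL:
        raise MLPError(f"input layer ({IL}) must be at least as wide as output ({OL})")
    if rule == "cube_root":
        kappa = (IL / OL) ** (1.0 / 3.0)
    elif rule == "sqrt":
        kappa = (IL / OL) ** 0.5
    else:
        raise MLPError(f"unknown sizing rule {rule!r}")
    hl1 = _round(OL * kappa ** 2)
    hl2 = _round(OL * kappa)
    hl1 = min(max(hl1, OL), IL)
    hl2 = min(max(hl2, OL), hl1)
    return MLPSpec(IL=IL, OL=OL, HL1=hl1, HL2=hl2)


@dataclass
class MLPSpec:
    """Architecture and training hyperparameters."""

    IL: int
    OL: int = 1
    HL1: int = 1
    HL2: int = 1
    epochs: int = 10
    threshold: float = 0.5
    learning_rate: float = 0.01
    batch_size: int = 32
    optimizer: str = "adam"  # or "sgd"
    momentum: float = 0.9    # sgd only
    seed: int = 0

    def __post_init__(self):
        if self.OL != 1:
            raise MLPError("binary classifier: output layer size must be 1")
        if not (self.IL >= self.HL1 >= self.HL2 >= self.OL >= 1):
            raise MLPError(
                f"layer sizes must form a pyramid IL >= HL1 >= HL2 >= OL, "
                f"got {self.IL} >= {self.HL1} >= {self.HL2} >= {self.OL}"
            )


class MLPModel:
    """A 2-hidden-layer ReLU network with sigmoid output, MSE-trained.

    Weights are seeded uniform symmetric per layer with 1/sqrt(fan_in)
    scaling. ``predict`` applies the inclusive decision rule
    ``sigmoid(z) >= threshold``.
    """

    def __init__(self, spec: MLPSpec):
        self.spec = spec
        self.trained = False
        self.mse_log: list[float] = []
        rng = np.random.default_rng(spec.seed)
        def init(n_in, n_out):
            lim = 1.0 / np.sqrt(n_in)
            return rng.uniform(-lim, lim, size=(n_in, n_out))
        self.W1 = init(spec.IL, spec.HL1)
        self.b1 = np.zeros(spec.HL1)
        self.W2 = init(spec.HL1, spec.HL2)
        self.b2 = np.zeros(spec.HL2)
        self.W3 = init(spec.HL2, spec.OL)
        self.b3 = np.zeros(spec.OL)
        self._rng = rng

    # -- forward ---------------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid outputs for a (n, IL) batch, shape (n,)."""
        h1 = relu(X @ self.W1 + self.b1)
        h2 = relu(h1 @ self.W2 + self.b2)
        return sigmoid(h2 @ self.W3 + self.b3).ravel()

    # -- training --------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPModel":
        """Minibatch gradient descent on MSE for ``spec.epochs`` passes.

        Logs the full-set MSE after each epoch. A single-class target set
        is tolerated (the wrapper's fitness handles degenerate outcomes).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) == 0:
            raise MLPError("empty training set")
        if X.shape[1] != self.spec.IL:
            raise MLPError(f"expected {self.spec.IL} features, got {X.shape[1]}")
        n = len(X)
        lr = self.spec.learning_rate
        mom = self.spec.momentum
        adam = self.spec.optimizer == "adam"
        if self.spec.optimizer not in ("adam", "sgd"):
            raise MLPError(f"unknown optimizer {self.spec.optimizer!r}")
        params = (self.W1, self.b1, self.W2, self.b2, self.W3, self.b3)
        vel = [np.zeros_like(w) for w in params]
        sq = [np.zeros_like(w) for w in params]
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        step = 0
        for _ in range(self.spec.epochs):
            order = self._rng.permutation(n)
            for beg in range(0, n, self.spec.batch_size):
                idx = order[beg:beg + self.spec.batch_size]
                xb, yb = X[idx], y[idx]
                m = len(idx)
                # forward with caches
                z1 = xb @ self.W1 + self.b1
                h1 = relu(z1)
                z2 = h1 @ self.W2 + self.b2
                h2 = relu(z2)
                out = sigmoid(h2 @ self.W3 + self.b3).ravel()
                # backward: d(MSE)/d(out) = 2 (out - y) / m
                d_out = (2.0 / m) * (out - yb) * out * (1.0 - out)
                d_out = d_out[:, None]
                gW3 = h2.T @ d_out
                gb3 = d_out.sum(axis=0)
                d2 = (d_out @ self.W3.T) * (z2 > 0)
                gW2 = h1.T @ d2
                gb2 = d2.sum(axis=0)
                d1 = (d2 @ self.W2.T) * (z1 > 0)
                gW1 = xb.T @ d1
                gb1 = d1.sum(axis=0)
                grads = (gW1, gb1, gW2, gb2, gW3, gb3)
                if adam:
                    step += 1
                    c1 = 1.0 - b1m ** step
                    c2 = 1.0 - b2m ** step
                    for v, s, p_, g_ in zip(vel, sq, params, grads):
                        v *= b1m; v += (1 - b1m) * g_
                        s *= b2m; s += (1 - b2m) * g_ * g_
                        p_ -= lr * (v / c1) / (np.sqrt(s / c2) + eps)
                else:
                    for v, p_, g_ in zip(vel, params, grads):
                        v *= mom
                        v += g_
                        p_ -= lr * v
            mse = float(np.mean((self.forward(X) - y) ** 2))
            self.mse_log.append(mse)
        self.trained = True
        return self

    # -- prediction ------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary labels for a (n, IL) batch (inclusive threshold)."""
        if not self.trained:
            raise MLPError("model must be trained before prediction")
        return (self.forward(np.atleast_2d(X)) >= self.spec.threshold).astype(np.int8)


def train(
    model: MLPModel, train_set, active_features: np.ndarray | None = None
) -> MLPModel:
    """Fit ``model`` on a :class:`~evoeeg.segment.WindowDataset`, using the
    channel-major flattening restricted to ``active_features``."""
    X = train_set.flattened(active_features)
    return model.fit(X, train_set.labels)


def predict(model: MLPModel, window, active_features: np.ndarray | None = None) -> int:
    """Binary label for a single :class:`~evoeeg.segment.Window`."""
    x = window.values.reshape(1, -1)
    if active_features is not None:
        x = x[:, active_features]
    return int(model.predict(x)[0])
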