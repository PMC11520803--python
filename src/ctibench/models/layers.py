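"""Minimal dense neural-network layers with explicit forward/backward passes.

Everything is plain NumPy in float32.  A layer caches what its backward pass
needs during ``forward``; ``backward`` receives the loss gradient w.r.t. the
layer output and returns the gradient w.r.t. its input, accumulating
parameter gradients in-place.  ``SGDOptimizer`` implements stochastic
gradient descent with classical momentum.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "ELU",
    "Sequential",
    "SGDOptimizer",
    "cross_entropy",
    "softmax",
]

EPS = 1e-7  # numerical clipping for log arguments


class Dense:
    """Affine layer y = x W + b with He-scaled Gaussian init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, scale, size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.W.T

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def parameters(self):
        return []


class ELU:
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._out = np.where(x > 0, x, self.alpha * np.expm1(x))
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * np.where(self._x > 0, 1.0, self._out + self.alpha)

    def parameters(self):
        return []


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class SGDOptimizer:
    """SGD with classical momentum over (param, grad) pairs."""

    def __init__(self, parameters, lr: float = 0.01, momentum: float = 0.9):
        self.parameters = list(parameters)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p, _ in self.parameters]

    def step(self) -> None:
        for (p, g), v in zip(self.parameters, self.velocity):
            v *= self.momentum
            v += g
            p -= self.lr * v

    def zero_grad(self) -> None:
        for _, g in self.parameters:
            g[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(y: np.ndarray, y_pred: np.ndarray, eps: float = EPS) -> float:
    """Mean binary cross-entropy -[y log y' + (1-y) log(1-y')].

    ``y_pred`` is the predicted probability of the positive class, clipped
    to (eps, 1-eps) before the logs.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(y_pred, dtype=np.float64), eps, 1.0 - eps)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log1p(-p))))
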