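"""Minimal neural-network engine (numpy, manual backprop).

Provides exactly the layers the edge-prediction models need: a kernel-size-1
"convolution" (a linear map over the trailing feature-channel axis, shared
across pair rows), batch normalization over all non-channel axes, ReLU,
inverted dropout, dense layers, a numerically stable weighted binary
cross-entropy with logits, and Adam with (coupled) L2 weight decay.

Gradients are derived by hand and verified against central finite
differences in the test suite.  Arrays are channels-last: a pair-feature
block has shape (batch, n_rows, n_channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Parameter",
    "Linear",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "Adam",
    "bce_with_logits",
]


@dataclass
class Parameter:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear:
    """Affine map over the last axis; all leading axes are batch-like.

    With a 3-D input (batch, rows, in_channels) this is a shared 1-D
    convolution of kernel size 1 mixing the feature channels of every row.
    """

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.w = Parameter(_fan_in_uniform(rng, (in_features, out_features), in_features))
        self.b = Parameter(_fan_in_uniform(rng, (out_features,), in_features))
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        xm = x.reshape(-1, x.shape[-1])
        gm = grad.reshape(-1, grad.shape[-1])
        self.w.grad += xm.T @ gm
        self.b.grad += gm.sum(axis=0)
        return grad @ self.w.value.T


class BatchNorm:
    """Batch normalization over every axis except the last (channel) axis.

    Training uses batch statistics (biased variance) and maintains running
    statistics (unbiased variance) for evaluation mode, so inference is
    deterministic and batch-independent.
    """

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            n = int(np.prod([x.shape[a] for a in axes]))
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            unbiased = var * (n / max(n - 1, 1))
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, axes, training)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, training = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        if not training:
            return g * inv_std
        n = int(np.prod([xhat.shape[a] for a in axes]))
        return inv_std * (g - g.mean(axis=axes) - xhat * (g * xhat).sum(axis=axes) / n)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(
    logits: np.ndarray, labels: np.ndarray, pos_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean weighted binary cross-entropy from logits, with its gradient.

    Per element: w * y * softplus(-z) + (1 - y) * softplus(z), averaged over
    all elements; ``pos_weight`` scales the positive-class term.  Stable for
    large |z| (log-sum-exp form).
    """
    z = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=float)
    if z.shape != y.shape:
        raise ValueError("logits and labels must have the same shape")
    if np.any((y != 0.0) & (y != 1.0)):
        raise ValueError("labels must be binary (0/1)")
    n = z.size
    loss = float((pos_weight * y * _softplus(-z) + (1.0 - y) * _softplus(z)).sum() / n)
    s = _sigmoid(z)
    grad = ((1.0 - y) * s - pos_weight * y * (1.0 - s)) / n
    return loss, grad


class Adam:
    """Adam with L2 weight decay added to the gradient (coupled decay)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 2e-4,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
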