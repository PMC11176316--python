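"""Minimal NumPy neural-network layers with manual backpropagation.

The pipeline only needs small dense/conv-1d stacks trained on desk-scale
problems, so a hand-rolled layer library keeps the package free of a deep
learning framework dependency.  Conventions follow the usual (N, C, L)
layout for 1-D feature maps and (N, D) for dense activations.

Every stochastic operation draws from an explicitly passed
``numpy.random.Generator`` so training is bit-reproducible under a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DimensionError, NumericalError

__all__ = [
    "Dense",
    "ReLU",
    "Sigmoid",
    "Conv1d",
    "BatchNorm1d",
    "MaxPool1d",
    "Flatten",
    "Dropout",
    "Sequential",
    "SGDMomentum",
    "Adam",
    "mse_loss",
    "bce_with_logits_loss",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base layer: holds ``params`` and matching ``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map (N, n_in) -> (N, n_out); He-normal init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_in, self.n_out = int(n_in), int(n_out)
        std = np.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0.0, std, size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, *, training=False, rng=None):
        if x.shape[1] != self.n_in:
            raise DimensionError(
                f"Dense expects {self.n_in} inputs, got {x.shape[1]}")
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._y = sigmoid(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Conv1d(Layer):
    """Valid (no padding) 1-D convolution, stride 1.

    Input (N, C_in, L) -> output (N, C_out, L - k + 1).
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = int(c_in), int(c_out), int(kernel_size)
        std = np.sqrt(2.0 / (c_in * kernel_size))
        self.params["W"] = rng.normal(0.0, std, size=(c_out, c_in, self.k))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, *, training=False, rng=None):
        if x.shape[1] != self.c_in:
            raise DimensionError(
                f"Conv1d expects {self.c_in} channels, got {x.shape[1]}")
        if x.shape[2] < self.k:
            raise DimensionError(
                f"Conv1d kernel {self.k} larger than input length {x.shape[2]}")
        # (N, C_in, L_out, k) windows
        self._xw = sliding_window_view(x, self.k, axis=2)
        self._in_shape = x.shape
        out = np.einsum("oik,nilk->nol", self.params["W"], self._xw,
                        optimize=True)
        return out + self.params["b"][None, :, None]

    def backward(self, grad):
        self.grads["W"] = np.einsum("nol,nilk->oik", grad, self._xw,
                                    optimize=True)
        self.grads["b"] = grad.sum(axis=(0, 2))
        dx = np.zeros(self._in_shape)
        l_out = grad.shape[2]
        for j in range(self.k):
            dx[:, :, j:j + l_out] += np.einsum(
                "nol,oi->nil", grad, self.params["W"][:, :, j], optimize=True)
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (N, C, L) or (N, D) inputs."""

    def __init__(self, n_channels: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.c = int(n_channels)
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(self.c)
        self.params["beta"] = np.zeros(self.c)
        self.running_mean = np.zeros(self.c)
        self.running_var = np.ones(self.c)

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _expand(self, v, x):
        return v if x.ndim == 2 else v[None, :, None]

    def forward(self, x, *, training=False, rng=None):
        axes = self._axes(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - self._expand(mean, x)) / self._expand(self._std, x)
        return (self._expand(self.params["gamma"], x) * self._xhat
                + self._expand(self.params["beta"], x))

    def backward(self, grad):
        x = self._xhat
        axes = self._axes(grad)
        m = np.prod([grad.shape[a] for a in axes])
        self.grads["gamma"] = (grad * x).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = self._expand(self.params["gamma"], grad)
        dxhat = grad * g
        # standard batch-norm backward in terms of xhat
        term = (dxhat
                - self._expand(dxhat.mean(axis=axes), grad)
                - x * self._expand((dxhat * x).mean(axis=axes), grad))
        return term / self._expand(self._std, grad)


class MaxPool1d(Layer):
    """Window-2 max pooling with floor division of the length."""

    def __init__(self, window: int = 2) -> None:
        super().__init__()
        self.w = int(window)

    def forward(self, x, *, training=False, rng=None):
        n, c, length = x.shape
        l_out = length // self.w
        self._in_shape = x.shape
        self._trunc = x[:, :, :l_out * self.w].reshape(n, c, l_out, self.w)
        self._argmax = self._trunc.argmax(axis=3)
        return self._trunc.max(axis=3)

    def backward(self, grad):
        n, c, l_out, w = self._trunc.shape
        dtr = np.zeros_like(self._trunc)
        idx = np.indices((n, c, l_out))
        dtr[idx[0], idx[1], idx[2], self._argmax] = grad
        dx = np.zeros(self._in_shape)
        dx[:, :, :l_out * w] = dtr.reshape(n, c, l_out * w)
        return dx


class Flatten(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def forward(self, x, *, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential:
    """Ordered layer container with forward/backward and parameter access."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters and BN statistics."""
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, val in layer.params.items():
                state[f"layer{i}.{name}"] = val
            if isinstance(layer, BatchNorm1d):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                key = f"layer{i}.{name}"
                arr = np.asarray(state[key])
                if arr.shape != layer.params[name].shape:
                    raise DimensionError(
                        f"checkpoint mismatch at {key}: stored {arr.shape}, "
                        f"model {layer.params[name].shape}")
                layer.params[name] = arr.copy()
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = np.asarray(
                    state[f"layer{i}.running_mean"]).copy()
                layer.running_var = np.asarray(
                    state[f"layer{i}.running_var"]).copy()


class SGDMomentum:
    """Classic momentum SGD: v <- mu*v - lr*g; p <- p + v."""

    def __init__(self, params: list[tuple[Layer, str]], lr: float,
                 momentum: float = 0.9) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._v = [np.zeros_like(layer.params[name]) for layer, name in params]

    def step(self) -> None:
        for (layer, name), v in zip(self.params, self._v):
            v *= self.momentum
            v -= self.lr * layer.grads[name]
            layer.params[name] = layer.params[name] + v


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[tuple[Layer, str]], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = [np.zeros_like(layer.params[name]) for layer, name in params]
        self._v = [np.zeros_like(layer.params[name]) for layer, name in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for (layer, name), m, v in zip(self.params, self._m, self._v):
            g = layer.grads[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            layer.params[name] = layer.params[name] - self.lr * mhat / (
                np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements; returns (loss, dloss/dpred)."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = 2.0 * diff / diff.size
    return loss, grad


def bce_with_logits_loss(logits: np.ndarray,
                         y: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on raw logits.

    Returns (mean loss, dloss/dlogits).
    """
    z = logits.ravel()
    t = y.ravel().astype(np.float64)
    if z.shape != t.shape:
        raise DimensionError("logits and labels differ in length")
    # log(1+exp(z)) computed stably
    loss_vec = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    loss = float(loss_vec.mean())
    if not np.isfinite(loss):
        raise NumericalError("non-finite classification loss")
    grad = (sigmoid(z) - t) / t.size
    return loss, grad.reshape(logits.shape)
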