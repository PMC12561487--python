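"""Minimal NCHW convolutional-network engine with manual backprop.

The translation networks in this package are small (tens of layers, desk
scale inputs), so they run on a compact numpy engine: each layer caches its
forward activations and implements an explicit backward pass; Adam carries
per-parameter moment state. Convolutions are evaluated as k*k shifted
matrix products, which BLAS handles efficiently at these sizes.

Conventions: float64 NCHW tensors; ``forward`` caches what ``backward``
needs; ``backward`` accumulates parameter gradients (call ``zero_grad``
between optimization steps) and returns the gradient w.r.t. its input.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "Tanh",
    "Upsample2x",
    "AvgPool2x",
    "Sequential",
    "ResBlock",
    "Adam",
]


class Layer:
    """Base layer: parameterless passthrough hooks."""

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, grad) triples; grads are accumulated in place."""
        return []

    def zero_grad(self) -> None:
        for _, _, g in self.params():
            g[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2D convolution ('same'-style zero padding, arbitrary stride).

    Weights use He initialization scaled for the fan-in; output side is
    ``(H + 2 pad - k) // stride + 1``.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        std = math.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, std, (cout, cin, k, k))
        self.b = np.zeros(cout)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def params(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp
        N, C, H, W = xp.shape
        Ho = (H - k) // s + 1
        Wo = (W - k) // s + 1
        cout = self.W.shape[0]
        out = np.empty((N, cout, Ho, Wo))
        out[:] = self.b[None, :, None, None]
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
                # (cout, cin) @ (cin, N*Ho*Wo)
                flat = xs.transpose(1, 0, 2, 3).reshape(C, -1)
                out += (
                    (self.W[:, :, i, j] @ flat)
                    .reshape(cout, N, Ho, Wo)
                    .transpose(1, 0, 2, 3)
                )
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._xp
        p, k, s = self.pad, self.k, self.stride
        N, C, H, W = xp.shape
        _, cout, Ho, Wo = grad.shape
        gflat = grad.transpose(1, 0, 2, 3).reshape(cout, -1)
        self.gb += grad.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
                flat = xs.transpose(1, 0, 2, 3).reshape(C, -1)
                self.gW[:, :, i, j] += gflat @ flat.T
                dslice = (
                    (self.W[:, :, i, j].T @ gflat)
                    .reshape(C, N, Ho, Wo)
                    .transpose(1, 0, 2, 3)
                )
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dslice
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over the spatial axes.

    Non-affine (no learned gain/bias), matching the common image-to-image
    GAN configuration.
    """

    def __init__(self, eps: float = 1e-5):
        self.eps = eps
        self._y: np.ndarray | None = None
        self._inv: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        y = (x - mu) * inv
        self._y, self._inv = y, inv
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        y, inv = self._y, self._inv
        m1 = grad.mean(axis=(2, 3), keepdims=True)
        m2 = (grad * y).mean(axis=(2, 3), keepdims=True)
        return inv * (grad - m1 - y * m2)


class ReLU(Layer):
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, grad):
        return grad * self._m


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x):
        self._m = x > 0
        return np.where(self._m, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._m, grad, self.alpha * grad)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        return (
            grad[:, :, 0::2, 0::2]
            + grad[:, :, 1::2, 0::2]
            + grad[:, :, 0::2, 1::2]
            + grad[:, :, 1::2, 1::2]
        )


class AvgPool2x(Layer):
    """2x2 average pooling (even input sides assumed)."""

    def forward(self, x):
        return 0.25 * (
            x[:, :, 0::2, 0::2]
            + x[:, :, 1::2, 0::2]
            + x[:, :, 0::2, 1::2]
            + x[:, :, 1::2, 1::2]
        )

    def backward(self, grad):
        return 0.25 * grad.repeat(2, axis=2).repeat(2, axis=3)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for i, lay in enumerate(self.layers):
            out.extend((f"{i}.{n}", v, g) for n, v, g in lay.params())
        return out

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad


class ResBlock(Layer):
    """conv-norm-relu-conv-norm with an identity skip (pix2pixHD style)."""

    def __init__(self, c: int, rng: np.random.Generator | None = None):
        self.body = Sequential(
            Conv2d(c, c, 3, rng=rng),
            InstanceNorm2d(),
            ReLU(),
            Conv2d(c, c, 3, rng=rng),
            InstanceNorm2d(),
        )

    def params(self):
        return self.body.params()

    def forward(self, x):
        return x + self.body.forward(x)

    def backward(self, grad):
        return grad + self.body.backward(grad)


class Adam:
    """Adam over the parameters of one or more layers."""

    def __init__(
        self,
        layers: list[Layer],
        lr: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.entries = []
        for lay in layers:
            self.entries.extend(lay.params())
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(v) for _, v, _ in self.entries]
        self.v = [np.zeros_like(v) for _, v, _ in self.entries]

    def zero_grad(self) -> None:
        for _, _, g in self.entries:
            g[...] = 0.0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (_, val, g), m, v in zip(self.entries, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            val -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for m, src in zip(self.m, state["m"]):
            m[...] = src
        for v, src in zip(self.v, state["v"]):
            v[...] = src
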