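"""Minimal NumPy neural-network engine with manual backpropagation.

Supports the layer types needed by the package's two networks: 2D
convolution (im2col), cross-channel local response normalization,
overlapping max-pooling, locally connected (unshared-weight) convolution,
dense layers, ReLU/sigmoid activations, and binary cross-entropy on logits,
optimized by mini-batch SGD with momentum. Array layout is ``(N, C, H, W)``.

Correctness of every backward pass is pinned by numerical gradient checks in
the test suite; this module favours clarity over raw speed and is intended
for the small patch datasets this package trains on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2D", "LocallyConnected2D", "LRN", "MaxPool2D", "Flatten",
    "Dense", "ReLU", "Sigmoid", "Sequential", "bce_with_logits", "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """Return patches of shape (N, C*k*k, oH*oW) and the padded input shape."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (N, C, oH, oW, k, k)
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols), (n, c, hp, wp, oh, ow)


def _col2im(cols: np.ndarray, shape_info: tuple, k: int, stride: int, pad: int,
            out_hw: tuple[int, int]) -> np.ndarray:
    """Scatter-add column gradients back to the input tensor."""
    n, c, hp, wp, oh, ow = shape_info
    grad = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            grad[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                cols6[:, :, i, j]
            )
    h, w = out_hw
    return grad[:, :, pad : pad + h, pad : pad + w]


class Layer:
    """Base layer; parameterized layers fill ``params``/``grads``."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in))
        self.b = np.zeros(out_ch)
        self.k, self.stride, self.pad = kernel, stride, pad
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x_hw = x.shape[2:]
        cols, info = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._info = cols, info
        n, _, _, _, oh, ow = info
        out = np.einsum("of,nfl->nol", self.W, cols) + self.b[None, :, None]
        return out.reshape(n, -1, oh, ow)

    def backward(self, gy):
        n, oc, oh, ow = gy.shape
        g = gy.reshape(n, oc, oh * ow)
        self.grads[0][...] = np.einsum("nol,nfl->of", g, self._cols)
        self.grads[1][...] = g.sum(axis=(0, 2))
        gcols = np.einsum("of,nol->nfl", self.W, g)
        return _col2im(gcols, self._info, self.k, self.stride, self.pad, self._x_hw)


class LocallyConnected2D(Layer):
    """Convolution-like layer with unshared weights per output location."""

    def __init__(self, in_ch: int, out_ch: int, in_hw: tuple[int, int],
                 kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        h, w = in_hw
        self.oh = (h - kernel) // stride + 1
        self.ow = (w - kernel) // stride + 1
        loc = self.oh * self.ow
        fan_in = in_ch * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (loc, out_ch, fan_in))
        self.b = np.zeros((loc, out_ch))
        self.k, self.stride = kernel, stride
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x_hw = x.shape[2:]
        cols, info = _im2col(x, self.k, self.stride, 0)
        self._cols, self._info = cols, info
        n = x.shape[0]
        out = np.einsum("nfl,lof->nlo", cols, self.W) + self.b[None]
        return out.transpose(0, 2, 1).reshape(n, -1, self.oh, self.ow)

    def backward(self, gy):
        n, oc, _, _ = gy.shape
        g = gy.reshape(n, oc, -1).transpose(0, 2, 1)  # (N, L, oc)
        self.grads[0][...] = np.einsum("nlo,nfl->lof", g, self._cols)
        self.grads[1][...] = g.sum(axis=0)
        gcols = np.einsum("nlo,lof->nfl", g, self.W)
        return _col2im(gcols, self._info, self.k, self.stride, 0, self._x_hw)


def _channel_window_sum(t: np.ndarray, n: int) -> np.ndarray:
    """Sliding sum over a symmetric channel window of size ``n`` (odd)."""
    half = n // 2
    padded = np.pad(t, ((0, 0), (half, half), (0, 0), (0, 0)))
    csum = np.cumsum(padded, axis=1)
    csum = np.pad(csum, ((0, 0), (1, 0), (0, 0), (0, 0)))
    c = t.shape[1]
    return csum[:, n : n + c] - csum[:, 0:c]


class LRN(Layer):
    """Cross-channel local response normalization (AlexNet-style)."""

    def __init__(self, size: int = 5, k: float = 2.0, alpha: float = 1e-4,
                 beta: float = 0.75):
        super().__init__()
        self.size, self.k, self.alpha, self.beta = size, k, alpha, beta

    def forward(self, x):
        self._x = x
        self._S = self.k + self.alpha * _channel_window_sum(x**2, self.size)
        self._y = x * self._S ** (-self.beta)
        return self._y

    def backward(self, gy):
        x, S, b = self._x, self._S, self.beta
        inner = gy * x * S ** (-b - 1.0)
        return gy * S ** (-b) - 2.0 * self.alpha * b * x * _channel_window_sum(
            inner, self.size
        )


class MaxPool2D(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2):
        super().__init__()
        self.k, self.stride = kernel, stride

    def forward(self, x):
        self._x_shape = x.shape
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        view = view[:, :, ::s, ::s]
        n_, c_, oh, ow = view.shape[:4]
        flat = view.reshape(n_, c_, oh, ow, k * k)
        self._arg = flat.argmax(axis=-1)
        self._ohw = (oh, ow)
        return flat.max(axis=-1)

    def backward(self, gy):
        n, c, h, w = self._x_shape
        oh, ow = self._ohw
        k, s = self.k, self.stride
        di, dj = np.unravel_index(self._arg, (k, k))
        rows = np.arange(oh)[None, None, :, None] * s + di
        cols = np.arange(ow)[None, None, None, :] * s + dj
        grad = np.zeros(self._x_shape)
        nn, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        nn = nn[:, :, None, None]
        cc = cc[:, :, None, None]
        np.add.at(grad, (nn, cc, rows, cols), gy)
        return grad


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 init_scale: float | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gy):
        self.grads[0][...] = self._x.T @ gy
        self.grads[1][...] = gy.sum(axis=0)
        return gy @ self.W.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._y = sigmoid(x)
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient w.r.t. logits."""
    z = logits.ravel().astype(np.float64)
    t = targets.ravel().astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    grad = ((sigmoid(z) - t) / z.size).reshape(logits.shape)
    return float(loss), grad


class Sequential:
    """Layer stack with SGD-momentum training support."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self._velocity = [
            [np.zeros_like(p) for p in layer.params] for layer in layers
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def step(self, lr: float, momentum: float = 0.9) -> None:
        for layer, vel in zip(self.layers, self._velocity):
            for p, g, v in zip(layer.params, layer.grads, vel):
                v *= momentum
                v -= lr * g
                p += v

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = weights[i]
                i += 1
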