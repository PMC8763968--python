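"""Minimal numpy CNN stack with manual backpropagation.

Provides exactly what the two-stage vesicle detector needs: 2-D convolution
(im2col), ReLU, 2x2 max pooling, global average pooling, dense layers,
softmax cross-entropy (per-image and per-pixel), and Adam. Layers cache
their forward inputs so a backward pass can be run either for training or
partially — down to the last convolutional feature maps — for Grad-CAM.

Everything is float32 numpy; for a fixed seed training is reproducible on a
given BLAS backend (reduction order is the backend's).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_xent",
    "pixel_softmax_xent",
]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, H', W', C*k*k) patches for a stride-1 kxk conv."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = h + 2 * pad - k + 1, w + 2 * pad - k + 1
    s = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, ho, wo, k, k), (s[0], s[1], s[2], s[3], s[2], s[3]), writeable=False
    )
    # (N, H', W', C, k, k) -> (N, H', W', C*k*k)
    return cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * k * k)


class Layer:
    params: tuple = ()
    grads: tuple = ()

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 kxk convolution with 'same' (pad=k//2) or 'valid' padding."""

    def __init__(self, cin: int, cout: int, k: int = 3, pad: str = "same",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(cout, cin, k, k)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.k, self.pad = k, (k // 2 if pad == "same" else 0)
        self.params = ("w", "b")

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._in_shape = x.shape
        cols = _im2col(x, self.k, self.pad)          # (N,H',W',C*k*k)
        self._cols = cols
        wmat = self.w.reshape(self.w.shape[0], -1)   # (cout, C*k*k)
        y = cols @ wmat.T + self.b                   # (N,H',W',cout)
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy):
        n, cout, ho, wo = dy.shape
        cin, k, pad = self.w.shape[1], self.k, self.pad
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 3, 1), dtype=DTYPE)
        self.db = dyt.sum(axis=(0, 1, 2))
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.dw = (dyt.reshape(-1, cout).T @ cols).reshape(self.w.shape)
        # dx = full correlation of dy with kernels flipped and transposed,
        # expressed as a second im2col matmul (pad k-1-pad)
        dcols = _im2col(np.ascontiguousarray(dy, dtype=DTYPE), k, k - 1 - pad)
        wback = np.ascontiguousarray(
            self.w[:, :, ::-1, ::-1].transpose(0, 2, 3, 1)).reshape(-1, cin)
        dx = (dcols @ wback).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(dx)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        win = (x.reshape(n, c, h // 2, 2, w // 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, h // 2, w // 2, 4))
        self._arg = win.argmax(axis=-1)  # first max wins ties, deterministic
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dy):
        n, c, ho, wo = dy.shape
        dwin = np.zeros((n, c, ho, wo, 4), dtype=dy.dtype)
        np.put_along_axis(dwin, self._arg[..., None], dy[..., None], axis=-1)
        dx = (dwin.reshape(n, c, ho, wo, 2, 2)
                  .transpose(0, 1, 2, 4, 3, 5)
                  .reshape(self._in_shape))
        return dx


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._in_shape
        return np.broadcast_to(dy[:, :, None, None], self._in_shape) / (h * w)


class Flatten(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout)).astype(DTYPE)
        self.b = np.zeros(nout, dtype=DTYPE)
        self.params = ("w", "b")

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray, stop_at: int = 0) -> np.ndarray:
        """Backprop `dy` through layers [stop_at:], returning the gradient
        with respect to the output of layer `stop_at - 1` (the input of
        layer `stop_at`). `stop_at=0` goes all the way to the network input."""
        for layer in self.layers[stop_at:][::-1]:
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        out = []
        for layer in self.layers:
            for name in layer.params:
                out.append((layer, name))
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": getattr(layer, name)
                for i, layer in enumerate(self.layers) for name in layer.params}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                setattr(layer, name, np.asarray(state[f"{i}.{name}"], dtype=DTYPE))


class Adam:
    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}

    def step(self):
        self.t += 1
        for layer, name in self.net.parameters():
            g = getattr(layer, "d" + name)
            key = (id(layer), name)
            m = self.m.get(key, 0.0) * self.b1 + (1 - self.b1) * g
            v = self.v.get(key, 0.0) * self.b2 + (1 - self.b2) * g * g
            self.m[key], self.v[key] = m, v
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p = getattr(layer, name)
            setattr(layer, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over (N, K) logits with integer labels.

    Returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    d = p.astype(DTYPE)
    d[np.arange(n), y] -= 1.0
    return loss, d / DTYPE(n)


def pixel_softmax_xent(logits: np.ndarray, y: np.ndarray, w_fg: float = 1.0):
    """Per-pixel cross-entropy for (N, K, H, W) logits and (N, H, W) labels.

    `w_fg` up-weights foreground (label 1) pixels; returns (loss, dlogits)."""
    n, k, h, wd = logits.shape
    p = softmax(logits, axis=1)
    weights = np.where(y == 1, w_fg, 1.0).astype(DTYPE)
    wsum = DTYPE(weights.sum())
    py = np.take_along_axis(p, y[:, None], axis=1)[:, 0]
    loss = float((-weights * np.log(np.clip(py, 1e-12, None))).sum() / wsum)
    onehot = np.zeros_like(p, dtype=DTYPE)
    np.put_along_axis(onehot, y[:, None], DTYPE(1.0), axis=1)
    d = (p.astype(DTYPE) - onehot) * weights[:, None] / wsum
    return loss, d
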