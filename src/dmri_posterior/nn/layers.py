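"""Layers with explicit forward/backward passes.

Convolutional tensors use the (batch, channels, height, width) layout.
Each layer caches what its backward pass needs; ``params()`` exposes
(parameter, gradient) pairs for the optimizers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list:
        return []


class Linear(Layer):
    """Affine map with Kaiming-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng, dtype=np.float32) -> None:
        bound = np.sqrt(6.0 / n_in)
        self.w = rng.uniform(-bound, bound, (n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv2d(Layer):
    """2D convolution (cross-correlation) via im2col, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: int,
                 rng, dtype=np.float32) -> None:
        fan_in = c_in * kernel * kernel
        bound = np.sqrt(6.0 / fan_in)
        self.w = rng.uniform(-bound, bound, (fan_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.c_in, self.c_out, self.k, self.pad = c_in, c_out, kernel, padding

    def forward(self, x, train=False):
        bsz, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._in_shape = x.shape
        self._padded_shape = xp.shape
        # (B, C, Ho, Wo, k, k) -> (B, Ho, Wo, C, k, k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5)
        ho, wo = cols.shape[1], cols.shape[2]
        self._cols = np.ascontiguousarray(cols).reshape(-1, self.c_in * k * k)
        out = self._cols @ self.w + self.b
        return out.reshape(bsz, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        bsz, _, ho, wo = grad.shape
        gflat = grad.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.gw[...] = self._cols.T @ gflat
        self.gb[...] = gflat.sum(axis=0)
        gcols = (gflat @ self.w.T).reshape(bsz, ho, wo, self.c_in,
                                           self.k, self.k)
        gx = np.zeros(self._padded_shape, dtype=grad.dtype)
        for di in range(self.k):
            for dj in range(self.k):
                gx[:, :, di:di + ho, dj:dj + wo] += \
                    gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        p = self.pad
        h, w = self._in_shape[2], self._in_shape[3]
        return gx[:, :, p:p + h, p:p + w]

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class MaxPool2d(Layer):
    """2×2 max pooling with stride 2 (truncates odd trailing rows/cols)."""

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, :, :2 * h2, :2 * w2].reshape(b, c, h2, 2, w2, 2)
        blocks = xc.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
        self._argmax = blocks.argmax(axis=-1)
        return blocks.max(axis=-1)

    def backward(self, grad):
        b, c, h2, w2 = grad.shape
        gblocks = np.zeros((b, c, h2, w2, 4), dtype=grad.dtype)
        np.put_along_axis(gblocks, self._argmax[..., None], grad[..., None],
                          axis=-1)
        gx_c = gblocks.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros(self._in_shape, dtype=grad.dtype)
        gx[:, :, :2 * h2, :2 * w2] = gx_c.reshape(b, c, 2 * h2, 2 * w2)
        return gx


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    # -- checkpointing -----------------------------------------------------
    def state(self) -> list:
        return [p.copy() for p, _ in self.params()]

    def load_state(self, state: list) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError("state does not match network parameters")
        for (p, _), saved in zip(params, state):
            p[...] = saved
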