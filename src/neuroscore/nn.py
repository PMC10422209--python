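"""Compact numpy neural-network layers with explicit backpropagation.

Layers cache forward activations and implement an exact reverse pass; the
encoder composes them into a residual network. No batch-coupled statistics
are used anywhere (no batch normalization), so inference embeddings are
batch-size independent by construction.

Convolutions use im2col + matrix multiplication, which keeps both passes
inside BLAS and fast enough for desk-scale CPU training.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold (B,C,H,W) into rows of flattened k x k patches."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    b, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B,C,Ho,Wo,k,k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo, (b, c, h, w)

def _col2im(dcols, padded_shape, k, stride, ho, wo, pad):
    """Scatter-add patch gradients back to the (padded) input."""
    b, c, h, w = padded_shape
    dx = np.zeros(padded_shape)
    d = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                d[:, :, :, :, i, j]
            )
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2d:
    """2D convolution, He-initialized; optional init gain for residual tails."""

    def __init__(self, c_in, c_out, k=3, stride=1, pad=1, rng=None, gain=1.0):
        rng = rng or np.random.default_rng()
        scale = gain * np.sqrt(2.0 / (c_in * k * k))
        self.w = Param(rng.normal(0.0, scale, (c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        cols, ho, wo, padded_shape = _im2col(x, self.k, self.stride, self.pad)
        c_out = self.w.value.shape[0]
        out = cols @ self.w.value.reshape(c_out, -1).T + self.b.value
        out = out.reshape(x.shape[0], ho, wo, c_out).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, ho, wo, padded_shape)
        return out

    def backward(self, dy):
        cols, ho, wo, padded_shape = self._cache
        c_out = self.w.value.shape[0]
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.w.grad += (dy_flat.T @ cols).reshape(self.w.value.shape)
        self.b.grad += dy_flat.sum(axis=0)
        dcols = dy_flat @ self.w.value.reshape(c_out, -1)
        return _col2im(dcols, padded_shape, self.k, self.stride, ho, wo, self.pad)


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class Linear:
    def __init__(self, d_in, d_out, bias=True, rng=None):
        rng = rng or np.random.default_rng()
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)))
        self.b = Param(np.zeros(d_out)) if bias else None
        self._x = None

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        if train:
            self._x = x
        out = x @ self.w.value
        if self.b is not None:
            out = out + self.b.value
        return out

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class GlobalAvgPool:
    """Mean over spatial dims; adapts to any input resolution."""

    def __init__(self):
        self._shape = None

    def parameters(self):
        return []

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        b, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class ResidualBlock:
    """Identity-skip block: relu(x + conv2(relu(conv1(x)))).

    The second convolution is initialized with a small gain so the block
    starts close to the identity, which stabilizes training without
    normalization layers.
    """

    def __init__(self, channels, rng=None):
        self.conv1 = Conv2d(channels, channels, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, rng=rng, gain=0.5)
        self.relu_out = ReLU()

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()

    def forward(self, x, train=False):
        h = self.conv1.forward(x, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        return self.relu_out.forward(x + h, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dh = self.conv2.backward(d)
        dh = self.relu1.backward(dh)
        dh = self.conv1.backward(dh)
        return d + dh


class L2Normalize:
    """Project vectors onto the unit hypersphere."""

    def __init__(self, eps=1e-12):
        self.eps = eps
        self._cache = None

    def parameters(self):
        return []

    def forward(self, x, train=False):
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        if np.any(norms < self.eps):
            raise FloatingPointError("zero-norm vector cannot be normalized")
        z = x / norms
        if train:
            self._cache = (z, norms)
        return z

    def backward(self, dz):
        z, norms = self._cache
        return (dz - z * (z * dz).sum(axis=1, keepdims=True)) / norms


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
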