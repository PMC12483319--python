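"""NumPy neural-network layers with manual backpropagation.

Activations are channels-last ``(batch, *spatial, channels)`` so the inner
products map onto BLAS matmuls. Works for 2D and 3D spatial shapes alike.
All parameters are float32.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["Conv", "ReLU", "Sigmoid", "MaxPool", "Upsample"]


class Layer:
    """Base: forward(x) caches what backward(grad) needs."""

    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv(Layer):
    """N-dimensional convolution, odd kernel, 'same' zero padding.

    Implemented as a loop over kernel offsets, each a (C_in, C_out)
    matmul against a shifted view of the padded input; the backward pass
    mirrors the same loop for both weight and input gradients.
    """

    def __init__(self, in_channels, out_channels, ndim, kernel_size=3, rng=None, scale=None):
        super().__init__()
        self.ndim = ndim
        self.k = kernel_size
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size**ndim
        std = scale if scale is not None else np.sqrt(2.0 / fan_in)
        shape = (kernel_size,) * ndim + (in_channels, out_channels)
        self.params["W"] = rng.normal(0.0, std, size=shape).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self._offsets = list(itertools.product(range(kernel_size), repeat=ndim))

    def _pad(self, x):
        p = self.k // 2
        pad = [(0, 0)] + [(p, p)] * self.ndim + [(0, 0)]
        return np.pad(x, pad)

    def _im2col(self, xp, spatial):
        """(B, *spatial, k**ndim * C_in) patch matrix, kernel-major order."""
        sw = np.lib.stride_tricks.sliding_window_view(
            xp, (self.k,) * self.ndim, axis=tuple(range(1, 1 + self.ndim))
        )
        # sw: (B, *spatial, C_in, *kernel) -> (B, *spatial, *kernel, C_in)
        nd = self.ndim
        order = (
            tuple(range(1 + nd))
            + tuple(range(2 + nd, 2 + 2 * nd))
            + (1 + nd,)
        )
        return np.ascontiguousarray(sw.transpose(order))

    def forward(self, x):
        spatial = x.shape[1:-1]
        xp = self._pad(x.astype(np.float32, copy=False))
        W, b = self.params["W"], self.params["b"]
        cin, cout = W.shape[-2], W.shape[-1]
        kdim = self.k**self.ndim * cin
        cols = self._im2col(xp, spatial).reshape(-1, kdim)
        out = cols @ W.reshape(kdim, cout) + b
        self._cache = (cols, spatial, x.shape)
        return out.reshape(x.shape[:-1] + (cout,))

    def backward(self, grad):
        cols, spatial, in_shape = self._cache
        W = self.params["W"]
        cin, cout = W.shape[-2], W.shape[-1]
        kdim = self.k**self.ndim * cin
        g2 = grad.reshape(-1, cout).astype(np.float32, copy=False)
        self.grads["W"] = (cols.T @ g2).reshape(W.shape)
        self.grads["b"] = g2.sum(axis=0)
        dcols = (g2 @ W.reshape(kdim, cout).T).reshape(
            (in_shape[0],) + tuple(spatial) + (self.k,) * self.ndim + (cin,)
        )
        p = self.k // 2
        gxp = np.zeros(
            (in_shape[0],) + tuple(s + 2 * p for s in spatial) + (cin,),
            dtype=np.float32,
        )
        for off in self._offsets:
            sl = (
                (slice(None),)
                + tuple(slice(d, d + s) for d, s in zip(off, spatial))
                + (slice(None),)
            )
            gxp[sl] += dcols[(Ellipsis,) + off + (slice(None),)]
        self._cache = None
        sl = (slice(None),) + tuple(slice(p, p + s) for s in spatial) + (slice(None),)
        return gxp[sl]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class Sigmoid(Layer):
    def forward(self, x):
        self._out = 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))
        return self._out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


def _interleave(shape_spatial, factors):
    out = []
    for s, f in zip(shape_spatial, factors):
        if s % f:
            raise ValueError(f"spatial extent {s} not divisible by pooling factor {f}")
        out.extend((s // f, f))
    return out


class MaxPool(Layer):
    """Max pooling with per-axis integer factors (e.g. (1, 2, 2))."""

    def __init__(self, factors):
        super().__init__()
        self.factors = tuple(int(f) for f in factors)

    def _fold(self, x):
        B, C = x.shape[0], x.shape[-1]
        spatial = x.shape[1:-1]
        nd = len(spatial)
        inter = _interleave(spatial, self.factors)
        x2 = x.reshape(B, *inter, C)
        order = (
            [0]
            + [1 + 2 * i for i in range(nd)]
            + [2 + 2 * i for i in range(nd)]
            + [1 + 2 * nd]
        )
        x3 = np.ascontiguousarray(x2.transpose(order))
        out_spatial = tuple(s // f for s, f in zip(spatial, self.factors))
        return x3.reshape(B, *out_spatial, int(np.prod(self.factors)), C), out_spatial, order

    def forward(self, x):
        folded, out_spatial, order = self._fold(x)
        self._idx = folded.argmax(axis=-2)
        self._in_shape = x.shape
        self._order = order
        out = np.take_along_axis(folded, self._idx[..., None, :], axis=-2)[..., 0, :]
        return out

    def backward(self, grad):
        B, C = self._in_shape[0], self._in_shape[-1]
        spatial = self._in_shape[1:-1]
        nd = len(spatial)
        out_spatial = tuple(s // f for s, f in zip(spatial, self.factors))
        folded = np.zeros(
            (B, *out_spatial, int(np.prod(self.factors)), C), dtype=np.float32
        )
        np.put_along_axis(folded, self._idx[..., None, :], grad[..., None, :], axis=-2)
        trans_shape = (
            [B]
            + [s // f for s, f in zip(spatial, self.factors)]
            + list(self.factors)
            + [C]
        )
        folded = folded.reshape(trans_shape)
        inv = np.argsort(self._order)
        x2 = folded.transpose(inv)
        return x2.reshape(self._in_shape)


class Upsample(Layer):
    """Nearest-neighbour upsampling by per-axis integer factors."""

    def __init__(self, factors):
        super().__init__()
        self.factors = tuple(int(f) for f in factors)

    def forward(self, x):
        out = x
        for ax, f in enumerate(self.factors):
            if f > 1:
                out = np.repeat(out, f, axis=1 + ax)
        return out

    def backward(self, grad):
        B, C = grad.shape[0], grad.shape[-1]
        spatial = grad.shape[1:-1]
        inter = _interleave(spatial, self.factors)
        g2 = grad.reshape(B, *inter, C)
        nd = len(spatial)
        g2 = g2.sum(axis=tuple(2 + 2 * i for i in range(nd)))
        return g2
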