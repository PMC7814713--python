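"""Differentiable layers operating on channels-last arrays (N, *spatial, C)."""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A trainable array with its accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> List[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ConvND(Layer):
    """N-dimensional convolution, odd kernel, "same" zero padding, stride 1.

    Forward flattens each receptive field into a row (im2col) and runs one
    GEMM; backward scatters the gradient back with one shifted addition per
    kernel offset.
    """

    def __init__(self, ndim: int, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: Optional[np.random.Generator] = None):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        rng = rng or np.random.default_rng()
        self.ndim, self.in_ch, self.out_ch, self.kernel = ndim, in_ch, out_ch, kernel
        fan_in = in_ch * kernel ** ndim
        w = rng.standard_normal((in_ch,) + (kernel,) * ndim + (out_ch,))
        self.w = Parameter(w * np.sqrt(2.0 / fan_in))  # He initialization
        self.b = Parameter(np.zeros(out_ch))
        self._cols: Optional[np.ndarray] = None
        self._x_shape: Optional[Tuple[int, ...]] = None

    def parameters(self) -> List[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        pad = self.kernel // 2
        spatial_axes = tuple(range(1, self.ndim + 1))
        if pad:
            widths = [(0, 0)] + [(pad, pad)] * self.ndim + [(0, 0)]
            xp = np.pad(x, widths)
        else:
            xp = x
        windows = sliding_window_view(xp, (self.kernel,) * self.ndim,
                                      axis=spatial_axes)
        # (N, *spatial, in_ch, *kernel) -> (N * voxels, in_ch * kernel^ndim)
        cols = np.ascontiguousarray(windows, dtype=np.float32).reshape(
            -1, self.in_ch * self.kernel ** self.ndim)
        self._x_shape = x.shape
        if training:
            self._cols = cols
        w2 = self.w.value.reshape(-1, self.out_ch)
        out = cols @ w2 + self.b.value
        return out.reshape(x.shape[:-1] + (self.out_ch,))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cols is not None, "forward(training=True) must precede backward"
        dout2 = dout.reshape(-1, self.out_ch).astype(np.float32)
        self.w.grad += (self._cols.T @ dout2).reshape(self.w.value.shape)
        self.b.grad += dout2.sum(axis=0)

        pad = self.kernel // 2
        spatial = self._x_shape[1:-1]
        padded_shape = (self._x_shape[0],) + tuple(s + 2 * pad for s in spatial) \
            + (self.in_ch,)
        dxp = np.zeros(padded_shape, dtype=np.float32)
        for idx in np.ndindex(*(self.kernel,) * self.ndim):
            w_k = self.w.value[(slice(None),) + idx + (slice(None),)]  # (Cin, Cout)
            contrib = dout @ w_k.T
            slicer = (slice(None),) + tuple(
                slice(i, i + s) for i, s in zip(idx, spatial)) + (slice(None),)
            dxp[slicer] += contrib
        if pad:
            crop = (slice(None),) + tuple(slice(pad, -pad) for _ in spatial) \
                + (slice(None),)
            return dxp[crop]
        return dxp


class MaxPool(Layer):
    """2x max-pooling per spatial axis; spatial sizes must be even."""

    def __init__(self, ndim: int):
        self.ndim = ndim
        self._idx: Optional[np.ndarray] = None
        self._in_shape: Optional[Tuple[int, ...]] = None

    def _to_windows(self, x: np.ndarray) -> np.ndarray:
        n, c = x.shape[0], x.shape[-1]
        spatial = x.shape[1:-1]
        shape = (n,)
        for s in spatial:
            shape += (s // 2, 2)
        shape += (c,)
        xr = x.reshape(shape)
        # move the size-2 window axes to the end, then flatten them
        win_axes = tuple(2 + 2 * i for i in range(self.ndim))
        keep_axes = (0,) + tuple(1 + 2 * i for i in range(self.ndim)) \
            + (2 * self.ndim + 1,)
        xr = xr.transpose(keep_axes + win_axes)
        return xr.reshape(xr.shape[: self.ndim + 2] + (2 ** self.ndim,))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if any(s % 2 for s in x.shape[1:-1]):
            raise ValueError(f"max-pool needs even spatial sizes, got {x.shape[1:-1]}")
        self._in_shape = x.shape
        xw = self._to_windows(x)
        idx = np.argmax(xw, axis=-1)
        if training:
            self._idx = idx
        return np.take_along_axis(xw, idx[..., np.newaxis], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._idx is not None and self._in_shape is not None
        dw = np.zeros(dout.shape + (2 ** self.ndim,), dtype=np.float32)
        np.put_along_axis(dw, self._idx[..., np.newaxis],
                          dout[..., np.newaxis].astype(np.float32), axis=-1)
        # invert the window flattening
        n, c = self._in_shape[0], self._in_shape[-1]
        half = tuple(s // 2 for s in self._in_shape[1:-1])
        dw = dw.reshape((n,) + half + (c,) + (2,) * self.ndim)
        # axes now: (0, half..., C, win...) -> interleave back
        order = [0]
        for i in range(self.ndim):
            order += [1 + i, self.ndim + 2 + i]
        order += [self.ndim + 1]
        dw = dw.transpose(order)
        return dw.reshape(self._in_shape)


class UpConv(Layer):
    """Transposed convolution, kernel 2, stride 2 (non-overlapping blocks)."""

    def __init__(self, ndim: int, in_ch: int, out_ch: int,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.ndim, self.in_ch, self.out_ch = ndim, in_ch, out_ch
        w = rng.standard_normal((in_ch,) + (2,) * ndim + (out_ch,))
        self.w = Parameter(w * np.sqrt(2.0 / in_ch))
        self.b = Parameter(np.zeros(out_ch))
        self._x: Optional[np.ndarray] = None

    def parameters(self) -> List[Parameter]:
        return [self.w, self.b]

    def _interleave(self, blocks: np.ndarray, spatial: Tuple[int, ...]) -> np.ndarray:
        # blocks: (N, *spatial, 2,...,2, C) -> (N, *2*spatial, C)
        order = [0]
        for i in range(self.ndim):
            order += [1 + i, 1 + self.ndim + i]
        order += [2 * self.ndim + 1]
        out = blocks.transpose(order)
        return out.reshape((blocks.shape[0],) + tuple(2 * s for s in spatial)
                           + (self.out_ch,))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        spatial = x.shape[1:-1]
        w2 = self.w.value.reshape(self.in_ch, -1)
        blocks = (x @ w2).reshape(x.shape[:-1] + (2,) * self.ndim + (self.out_ch,))
        return self._interleave(blocks, spatial) + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._x is not None
        x = self._x
        spatial = x.shape[1:-1]
        n, c = dout.shape[0], dout.shape[-1]
        self.b.grad += dout.reshape(-1, c).sum(axis=0)
        # undo interleaving: (N, *2*spatial, C) -> (N, *spatial, 2...2, C)
        shape = (n,)
        for s in spatial:
            shape += (s, 2)
        shape += (c,)
        dblocks = dout.reshape(shape)
        keep = (0,) + tuple(1 + 2 * i for i in range(self.ndim))
        win = tuple(2 + 2 * i for i in range(self.ndim))
        dblocks = dblocks.transpose(keep + win + (2 * self.ndim + 1,))
        dflat = dblocks.reshape(-1, 2 ** self.ndim * c)
        xflat = x.reshape(-1, self.in_ch)
        self.w.grad += (xflat.T @ dflat).reshape(self.w.value.shape)
        return (dflat @ self.w.value.reshape(self.in_ch, -1).T).reshape(x.shape)


class BatchNorm(Layer):
    """Batch normalization over all axes but the channel axis."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def parameters(self) -> List[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat.astype(np.float32), inv_std.astype(np.float32))
        return (self.gamma.value * xhat + self.beta.value).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv_std = self._cache
        axes = tuple(range(dout.ndim - 1))
        m = np.prod([dout.shape[a] for a in axes])
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        return (inv_std * (dxhat - dxhat.mean(axis=axes)
                           - xhat * (dxhat * xhat).sum(axis=axes) / m)
                ).astype(np.float32)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity at prediction time."""

    def __init__(self, rate: float, rng: Optional[np.random.Generator] = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Softmax(Layer):
    """Channel-axis softmax producing a per-voxel class distribution."""

    def __init__(self) -> None:
        self._probs: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z, dtype=np.float64)
        probs = (e / e.sum(axis=-1, keepdims=True)).astype(np.float32)
        self._probs = probs
        return probs

    def backward(self, dprobs: np.ndarray) -> np.ndarray:
        assert self._probs is not None
        p = self._probs.astype(np.float64)
        g = np.asarray(dprobs, dtype=np.float64)
        return (p * (g - (g * p).sum(axis=-1, keepdims=True))).astype(np.float32)
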