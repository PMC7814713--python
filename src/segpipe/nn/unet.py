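"""The standard 2D/3D U-Net graph built from the backend layers.

Encoder: ``depth`` levels of two 3^n convolutions (ReLU, optional batch
norm and dropout) followed by 2x max-pooling, with filters doubling per
level from ``base_filters``.  A two-convolution bottleneck sits below.
Decoder: per level a stride-2 transposed convolution, channel concatenation
with the same-level encoder output (skip connection), and two convolutions.
A kernel-1 convolution maps to ``n_classes`` channels and a channel softmax
yields a per-voxel class distribution.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .layers import (BatchNorm, ConvND, Dropout, Layer, MaxPool, Parameter,
                     ReLU, Softmax, UpConv)


class _ConvBlock(Layer):
    """conv -> (batch norm) -> ReLU -> (dropout)."""

    def __init__(self, ndim: int, in_ch: int, out_ch: int, batch_norm: bool,
                 dropout: float, rng: np.random.Generator):
        self.conv = ConvND(ndim, in_ch, out_ch, kernel=3, rng=rng)
        self.bn = BatchNorm(out_ch) if batch_norm else None
        self.relu = ReLU()
        self.drop = Dropout(dropout, rng=rng) if dropout > 0 else None

    def parameters(self) -> List[Parameter]:
        params = self.conv.parameters()
        if self.bn is not None:
            params += self.bn.parameters()
        return params

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = self.conv.forward(x, training)
        if self.bn is not None:
            x = self.bn.forward(x, training)
        x = self.relu.forward(x, training)
        if self.drop is not None:
            x = self.drop.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.drop is not None:
            dout = self.drop.backward(dout)
        dout = self.relu.backward(dout)
        if self.bn is not None:
            dout = self.bn.backward(dout)
        return self.conv.backward(dout)


class UNet:
    def __init__(self, ndim: int, in_channels: int, n_classes: int,
                 base_filters: int, depth: int, batch_norm: bool = False,
                 dropout: float = 0.0, seed: int = 0):
        self.ndim = ndim
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.base_filters = base_filters
        self.depth = depth
        rng = np.random.default_rng(seed)

        filters = [base_filters * 2 ** i for i in range(depth + 1)]
        self.enc_blocks: List[List[_ConvBlock]] = []
        self.pools: List[MaxPool] = []
        ch = in_channels
        for i in range(depth):
            self.enc_blocks.append([
                _ConvBlock(ndim, ch, filters[i], batch_norm, dropout, rng),
                _ConvBlock(ndim, filters[i], filters[i], batch_norm, dropout, rng),
            ])
            self.pools.append(MaxPool(ndim))
            ch = filters[i]
        self.bottleneck = [
            _ConvBlock(ndim, ch, filters[depth], batch_norm, dropout, rng),
            _ConvBlock(ndim, filters[depth], filters[depth], batch_norm, dropout, rng),
        ]
        self.upconvs: List[UpConv] = []
        self.dec_blocks: List[List[_ConvBlock]] = []
        ch = filters[depth]
        for i in reversed(range(depth)):
            self.upconvs.append(UpConv(ndim, ch, filters[i], rng=rng))
            self.dec_blocks.append([
                _ConvBlock(ndim, 2 * filters[i], filters[i], batch_norm, dropout, rng),
                _ConvBlock(ndim, filters[i], filters[i], batch_norm, dropout, rng),
            ])
            ch = filters[i]
        self.final = ConvND(ndim, base_filters, n_classes, kernel=1, rng=rng)
        self.softmax = Softmax()
        self._skip_channels = [filters[i] for i in reversed(range(depth))]

    # ------------------------------------------------------------------ api

    def parameters(self) -> List[Parameter]:
        params: List[Parameter] = []
        for blocks in self.enc_blocks:
            for b in blocks:
                params += b.parameters()
        for b in self.bottleneck:
            params += b.parameters()
        for up, blocks in zip(self.upconvs, self.dec_blocks):
            params += up.parameters()
            for b in blocks:
                params += b.parameters()
        params += self.final.parameters()
        return params

    def num_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        skips = []
        for blocks, pool in zip(self.enc_blocks, self.pools):
            for b in blocks:
                x = b.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        for b in self.bottleneck:
            x = b.forward(x, training)
        for up, blocks, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            x = up.forward(x, training)
            x = np.concatenate([x, skip], axis=-1)
            for b in blocks:
                x = b.forward(x, training)
        x = self.final.forward(x, training)
        return self.softmax.forward(x, training)

    def backward(self, dprobs: np.ndarray) -> np.ndarray:
        d = self.softmax.backward(dprobs)
        d = self.final.backward(d)
        skip_grads: List[Optional[np.ndarray]] = [None] * self.depth
        # decoder ran levels depth-1 .. 0; walk it in reverse
        for j in reversed(range(self.depth)):
            for b in reversed(self.dec_blocks[j]):
                d = b.backward(d)
            f = self._skip_channels[j]
            d_up, d_skip = d[..., :f], d[..., f:]
            level = self.depth - 1 - j  # encoder level this skip came from
            skip_grads[level] = np.ascontiguousarray(d_skip)
            d = self.upconvs[j].backward(np.ascontiguousarray(d_up))
        for b in reversed(self.bottleneck):
            d = b.backward(d)
        for level in reversed(range(self.depth)):
            d = self.pools[level].backward(d)
            d = d + skip_grads[level]
            for b in reversed(self.enc_blocks[level]):
                d = b.backward(d)
        return d
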