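"""Hybrid attention module at the network bottleneck.

The ViT-stream output Fv (C, H/4, W/4) is bilinearly resized down to the
spatial size of F4 (8C, H/32, W/32), the two maps are concatenated to 9C
channels and a 1x1 convolution reduces them to C' = 9C/4 channels, giving
the fused feature Ff.  Two residual attention branches then act in parallel:

* channel attention: reshape Ff to a (C', S) matrix (S spatial positions),
  form the C'xC' Gram matrix, normalise each row with a softmax to get a
  stochastic channel-mixing matrix Wc, and set  Fc = Wc @ Ff + Ff;
* spatial attention: a 1x1 convolution reduces Ff to one channel, a softmax
  over all S positions turns it into a spatial weight map, which multiplies
  Ff (broadcast over channels):  Fs = softmax(conv(Ff)) * Ff + Ff.

Fc + Fs is restored to 8C channels by a final 1x1 convolution, producing the
enhanced bottleneck feature Fcv.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from ._autodiff import functional as F
from ._autodiff.nn import Conv2d, Module

__all__ = [
    "FusedFeature",
    "channel_attention",
    "SpatialAttention",
    "spatial_attention",
    "HybridAttention",
]


@dataclass
class FusedFeature:
    ff: Tensor   # (N, 9C/4, H/32, W/32)
    fc: Tensor   # channel-attended, same shape
    fs: Tensor   # spatially-attended, same shape
    fcv: Tensor  # (N, 8C, H/32, W/32)


def channel_attention(ff: Tensor, return_weights: bool = False):
    """Gram-matrix channel attention with residual add (parameter-free)."""
    n, c, h, w = ff.shape
    flat = ff.reshape(n, c, h * w)
    gram = flat @ flat.transpose(0, 2, 1)  # (N, C', C')
    wc = F.softmax(gram, axis=-1)  # each row a stochastic mixing distribution
    fc = (wc @ flat).reshape(n, c, h, w) + ff
    if return_weights:
        return fc, wc
    return fc


class SpatialAttention(Module):
    """1x1 conv to one channel, softmax over spatial positions, weighted residual."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(channels, 1, 1, rng=rng, dtype=dtype)

    def weight_map(self, x: Tensor) -> Tensor:
        """The normalised spatial weight map (N, 1, H, W); sums to 1 over H*W."""
        n, _, h, w = x.shape
        logits = self.conv(x).reshape(n, 1, h * w)
        return F.softmax(logits, axis=-1).reshape(n, 1, h, w)

    def forward(self, x: Tensor) -> Tensor:
        return self.weight_map(x) * x + x


def spatial_attention(ff: Tensor, module: SpatialAttention | None = None) -> Tensor:
    if module is None:
        module = SpatialAttention(ff.shape[1])
    return module(ff)


class HybridAttention(Module):
    """Fuse Fv with F4 and enhance the result with parallel channel/spatial attention."""

    def __init__(self, base_width: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        c = base_width
        if (9 * c) % 4:
            raise ValueError(f"9C must be divisible by 4; got C={c}")
        self.base_width = c
        self.reduced = 9 * c // 4
        self.fuse_conv = Conv2d(9 * c, self.reduced, 1, rng=rng, dtype=dtype)
        self.spatial = SpatialAttention(self.reduced, rng=rng, dtype=dtype)
        self.restore_conv = Conv2d(self.reduced, 8 * c, 1, rng=rng, dtype=dtype)

    def fuse_streams(self, fv: Tensor, f4: Tensor) -> Tensor:
        c = self.base_width
        if fv.shape[1] != c:
            raise ValueError(f"Fv has {fv.shape[1]} channels, expected C={c}")
        if f4.shape[1] != 8 * c:
            raise ValueError(f"F4 has {f4.shape[1]} channels, expected 8C={8 * c}")
        fv_small = F.bilinear_resize(fv, (f4.shape[2], f4.shape[3]))
        return self.fuse_conv(concat([fv_small, f4], axis=1))

    def forward(self, fv: Tensor, f4: Tensor) -> FusedFeature:
        ff = self.fuse_streams(fv, f4)
        fc = channel_attention(ff)
        fs = self.spatial(ff)
        fcv = self.restore_conv(fc + fs)
        return FusedFeature(ff=ff, fc=fc, fs=fs, fcv=fcv)


def ham_forward(module: HybridAttention, fv: Tensor, f4: Tensor) -> Tensor:
    """Functional alias returning only the enhanced bottleneck feature Fcv."""
    return module(fv, f4).fcv
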