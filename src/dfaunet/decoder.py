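"""Feature-enhanced residual decoder.

The enhanced bottleneck feature Fcv is injected into every encoder scale:

    F'di = Conv1x1( Up(Conv1x1(Fcv)) + Fi ),    i = 1..4

where the inner 1x1 convolution matches Fcv to Fi's channel count, Up is
bilinear interpolation to Fi's spatial size, and the outer 1x1 convolution
brings the sum to C/2 channels.  Decoding then walks up from the coarsest
scale with three parallel branches per stage:

    Fo_i = Convs(F'di (+) Fup) + Fup + SA(Fup) * F'di

with Fup the bilinearly up-sampled previous decoder output, (+) channel
concatenation, Convs a stack of base conv blocks (conv3x3 -> BN -> leaky
ReLU), and SA the one-channel spatial-softmax weight map.  A 1x1 convolution
plus 4x bilinear up-sampling and a sigmoid turn the final stage into a
probability map; the binary prediction thresholds it at 0.5.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat
from ._autodiff import functional as F
from ._autodiff.nn import Conv2d, Module
from .ham import SpatialAttention
from .vit import BaseConvBlock

__all__ = ["BottleneckFusion", "DecoderBlock", "SegmentationHead"]


class BottleneckFusion(Module):
    """Fuse Fcv into encoder scale i (the F'di computation)."""

    def __init__(self, base_width: int, scale_index: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if scale_index not in (1, 2, 3, 4):
            raise IndexError(f"scale index must be 1..4, got {scale_index}")
        super().__init__()
        c = base_width
        ci = 2 ** (scale_index - 1) * c
        self.scale_index = scale_index
        self.inner_conv = Conv2d(8 * c, ci, 1, rng=rng, dtype=dtype)
        self.outer_conv = Conv2d(ci, c // 2, 1, rng=rng, dtype=dtype)

    def forward(self, fcv: Tensor, fi: Tensor) -> Tensor:
        up = F.bilinear_resize(self.inner_conv(fcv), (fi.shape[2], fi.shape[3]))
        return self.outer_conv(up + fi)


class DecoderBlock(Module):
    """One FRD stage: concat/conv branch + residual branch + attention-gated branch."""

    def __init__(
        self,
        channels: int,
        hidden: int | None = None,
        num_blocks: int = 2,
        leaky_slope: float = 0.01,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        if num_blocks not in (1, 2):
            raise ValueError("num_blocks must be 1 or 2")
        inc = 2 * channels  # concatenation of F'di and Fup
        if num_blocks == 1:
            self.convs = [BaseConvBlock(inc, channels, leaky_slope, rng, dtype)]
        else:
            hidden = hidden or 2 * channels
            self.convs = [
                BaseConvBlock(inc, hidden, leaky_slope, rng, dtype),
                BaseConvBlock(hidden, channels, leaky_slope, rng, dtype),
            ]
        self.sa = SpatialAttention(channels, rng=rng, dtype=dtype)

    def forward(self, fd_prime: Tensor, previous: Tensor) -> Tensor:
        if previous.shape[1] != fd_prime.shape[1]:
            raise ValueError(
                f"channel mismatch: previous has {previous.shape[1]}, "
                f"stage expects {fd_prime.shape[1]}"
            )
        fup = F.bilinear_resize(previous, (fd_prime.shape[2], fd_prime.shape[3]))
        branch1 = concat([fd_prime, fup], axis=1)
        for block in self.convs:
            branch1 = block(branch1)
        branch2 = self.sa.weight_map(fup) * fd_prime
        return branch1 + fup + branch2


class SegmentationHead(Module):
    """1x1 conv to one channel, 4x bilinear up-sampling, sigmoid."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(channels, 1, 1, rng=rng, dtype=dtype)

    def logits(self, fo1: Tensor, out_size: tuple[int, int]) -> Tensor:
        return F.bilinear_resize(self.conv(fo1), out_size)

    def forward(self, fo1: Tensor, out_size: tuple[int, int],
                threshold: float = 0.5) -> tuple[Tensor, Tensor, np.ndarray]:
        logits = self.logits(fo1, out_size)
        prob_map = F.sigmoid(logits)
        pred_mask = (prob_map.data >= threshold).astype(np.uint8)
        return logits, prob_map, pred_mask
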