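"""Lightweight vision-transformer stream of the dual-stream encoder.

The stream consumes the first CNN feature map F1 (C, H/4, W/4), splits it
into two channel halves, and runs each half through patch attention at a
different granularity: a fine branch with patch size P=4 and a coarse branch
with P=16.  Each half is projected to a (C/2, H/4P, W/4P) token grid by a
learned per-channel linear map over each non-overlapping PxP patch, passed
through convolutional multi-head self-attention (scaled dot-product,
softmax(QK^T/sqrt(dk))V, with Q/K/V produced by 1x1 convolutions over the
token grid), and projected back to the half's original resolution.  The
re-assembled map F_MHA feeds a convolutional feed-forward block (two
conv3x3 -> batch-norm -> leaky-ReLU modules) giving F_FF, and the stream
output is the triple residual sum

    Fv = F1 + F_MHA + F_FF

so Fv keeps exactly the shape of F1.  The per-channel patch projections keep
the stream lightweight: well under 1% of the assembled model's parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from ._autodiff import functional as F
from ._autodiff.nn import BatchNorm2d, Conv2d, Module, Sequential
from ._autodiff.tensor import Parameter

__all__ = [
    "TokenGrid",
    "VitOutput",
    "PatchProjection",
    "ConvMultiHeadAttention",
    "FeedForward",
    "VitStream",
]


@dataclass
class TokenGrid:
    """A (C/2, H/4P, W/4P) grid of patch tokens from one channel half of F1."""

    tokens: Tensor
    patch_size: int
    origin_channels: slice


@dataclass
class VitOutput:
    fv: Tensor
    f_mha: Tensor
    f_ff: Tensor


class PatchProjection(Module):
    """Learned per-channel linear projection between pixels and patch tokens.

    ``project`` maps (N, C, H, W) -> (N, C, H/P, W/P): each PxP patch of each
    channel is reduced by a channel-specific weight vector of length P^2.
    ``unproject`` is the learned inverse, distributing each token back over
    its PxP footprint with a second weight vector.
    """

    def __init__(self, channels: int, patch_size: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        p2 = patch_size * patch_size
        bound = 1.0 / np.sqrt(p2)
        self.patch_size = patch_size
        self.weight_in = Parameter(
            rng.uniform(-bound, bound, (channels, p2)).astype(dtype) + 1.0 / p2
        )  # biased toward patch averaging at init
        self.bias_in = Parameter(np.zeros((channels, 1, 1), dtype))
        self.weight_out = Parameter(
            rng.uniform(-bound, bound, (channels, p2)).astype(dtype) + 1.0
        )  # biased toward broadcast at init
        self.bias_out = Parameter(np.zeros((channels, 1, 1), dtype))

    def _to_patches(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        p = self.patch_size
        if h % p or w % p:
            raise ValueError(f"spatial size ({h},{w}) not divisible by patch {p}")
        x = x.reshape(n, c, h // p, p, w // p, p)
        x = x.transpose(0, 1, 2, 4, 3, 5)
        return x.reshape(n, c, h // p, w // p, p * p)

    def project(self, x: Tensor) -> Tensor:
        patches = self._to_patches(x)  # N C Hp Wp P^2
        w = self.weight_in.reshape(1, self.weight_in.shape[0], 1, 1,
                                   self.weight_in.shape[1])
        return (patches * w).sum(axis=-1) + self.bias_in

    def unproject(self, tokens: Tensor) -> Tensor:
        n, c, hp, wp = tokens.shape
        p = self.patch_size
        w = self.weight_out.reshape(1, c, 1, 1, p * p)
        patches = tokens.reshape(n, c, hp, wp, 1) * w
        patches = patches.reshape(n, c, hp, wp, p, p).transpose(0, 1, 2, 4, 3, 5)
        return patches.reshape(n, c, hp * p, wp * p) + self.bias_out


def patchify(f1_half: Tensor, patch_size: int, projection: PatchProjection,
             origin: slice | None = None) -> TokenGrid:
    """Project one channel half of F1 onto its patch-token grid."""
    if projection.patch_size != patch_size:
        raise ValueError("projection was built for a different patch size")
    tokens = projection.project(f1_half)
    return TokenGrid(tokens, patch_size, origin or slice(None))


class ConvMultiHeadAttention(Module):
    """Multi-head scaled dot-product self-attention over a token grid.

    Q, K and V come from 1x1 convolutions over the (N, C, Hp, Wp) grid;
    attention runs over the flattened token positions, independently per
    head, with dk = C / heads.  A 1x1 output projection mixes the heads.
    """

    def __init__(self, channels: int, heads: int = 4,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if channels % heads:
            raise ValueError(f"heads={heads} must divide channels={channels}")
        rng = rng or np.random.default_rng(0)
        self.heads = heads
        self.q_conv = Conv2d(channels, channels, 1, rng=rng, dtype=dtype)
        self.k_conv = Conv2d(channels, channels, 1, rng=rng, dtype=dtype)
        self.v_conv = Conv2d(channels, channels, 1, rng=rng, dtype=dtype)
        self.out_conv = Conv2d(channels, channels, 1, rng=rng, dtype=dtype)
        self.last_weights: np.ndarray | None = None

    def forward(self, tokens: Tensor) -> Tensor:
        n, c, hp, wp = tokens.shape
        h = self.heads
        dk = c // h
        t = hp * wp

        def heads_view(x: Tensor) -> Tensor:
            # (N, C, Hp, Wp) -> (N, heads, T, dk)
            return x.reshape(n, h, dk, t).transpose(0, 1, 3, 2)

        q = heads_view(self.q_conv(tokens))
        k = heads_view(self.k_conv(tokens))
        v = heads_view(self.v_conv(tokens))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        weights = F.softmax(scores, axis=-1)  # rows sum to 1 over key positions
        self.last_weights = weights.data
        attended = weights @ v  # (N, heads, T, dk)
        out = attended.transpose(0, 1, 3, 2).reshape(n, c, hp, wp)
        return self.out_conv(out)


def multi_head_attention(tokens: TokenGrid, heads: int,
                         module: ConvMultiHeadAttention | None = None) -> TokenGrid:
    """Apply (or build and apply) convolutional multi-head attention to a grid."""
    if module is None:
        module = ConvMultiHeadAttention(tokens.tokens.shape[1], heads)
    out = module(tokens.tokens)
    return TokenGrid(out, tokens.patch_size, tokens.origin_channels)


class BaseConvBlock(Module):
    """conv3x3 -> batch-norm -> leaky-ReLU (the base convolutional module)."""

    def __init__(self, in_channels: int, out_channels: int, leaky_slope: float = 0.01,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, padding=1, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(out_channels, dtype=dtype)
        self.leaky_slope = leaky_slope

    def forward(self, x: Tensor) -> Tensor:
        return F.leaky_relu(self.bn(self.conv(x)), self.leaky_slope)


class FeedForward(Module):
    """Two base convolutional modules, shape preserving."""

    def __init__(self, channels: int, leaky_slope: float = 0.01,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.block1 = BaseConvBlock(channels, channels, leaky_slope, rng, dtype)
        self.block2 = BaseConvBlock(channels, channels, leaky_slope, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))


class VitStream(Module):
    """The full ViT stream: split, two-scale patch attention, FF, residual sum."""

    def __init__(
        self,
        channels: int,
        heads: int = 4,
        patch_sizes: tuple[int, int] = (4, 16),
        leaky_slope: float = 0.01,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if channels % 2:
            raise ValueError(f"F1 channel count {channels} must be even to split")
        super().__init__()
        rng = rng or np.random.default_rng(0)
        half = channels // 2
        self.patch_sizes = tuple(patch_sizes)
        self.projections = [
            PatchProjection(half, p, rng=rng, dtype=dtype) for p in self.patch_sizes
        ]
        self.attentions = [
            ConvMultiHeadAttention(half, heads, rng=rng, dtype=dtype)
            for _ in self.patch_sizes
        ]
        self.feed_forward = FeedForward(channels, leaky_slope, rng=rng, dtype=dtype)

    def forward(self, f1: Tensor) -> VitOutput:
        c = f1.shape[1]
        half = c // 2
        halves = [f1[:, :half], f1[:, half:]]
        branch_outputs = []
        for half_map, p, proj, attn in zip(
            halves, self.patch_sizes, self.projections, self.attentions
        ):
            grid = patchify(half_map, p, proj)
            attended = attn(grid.tokens)
            branch_outputs.append(proj.unproject(attended))
        f_mha = concat(branch_outputs, axis=1)
        f_ff = self.feed_forward(f_mha)
        fv = f1 + f_mha + f_ff
        return VitOutput(fv=fv, f_mha=f_mha, f_ff=f_ff)


def vit_forward(stream: VitStream, f1: Tensor) -> VitOutput:
    """Functional alias for ``stream(f1)``."""
    return stream(f1)
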