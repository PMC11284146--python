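"""Convolutional stream of the dual-stream encoder.

A ConvNeXt backbone produces a four-scale feature pyramid F1..F4 from an RGB
image batch.  The reference configuration is ConvNeXt-Base — base width
C=128, stage widths C, 2C, 4C, 8C and stage depths 3/3/27/3 — which is the
only ConvNeXt variant whose base width matches C=128.  Each stage halves the
spatial size and doubles the channel count:

    F1: (C,  H/4,  W/4)     F2: (2C, H/8,  W/8)
    F3: (4C, H/16, W/16)    F4: (8C, H/32, W/32)

No classification head is attached; the stage outputs are exposed directly.
Externally obtained pretrained weights can be loaded from a serialized
state-dictionary file (an ``.npz`` mapping parameter names to arrays), but
nothing in this package requires them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, as_tensor
from ._autodiff import functional as F
from ._autodiff.nn import Conv2d, LayerNorm2d, Module, trunc_normal
from ._autodiff.tensor import Parameter

__all__ = [
    "FeaturePyramid",
    "ConvNextBlock",
    "ConvNextEncoder",
    "build_convnext_encoder",
    "forward_pyramid",
]

CONVNEXT_BASE_DEPTHS = (3, 3, 27, 3)


@dataclass
class FeaturePyramid:
    """The four CNN-stream outputs with their scale contract."""

    f1: Tensor  # (N, C,  H/4,  W/4)
    f2: Tensor  # (N, 2C, H/8,  W/8)
    f3: Tensor  # (N, 4C, H/16, W/16)
    f4: Tensor  # (N, 8C, H/32, W/32)
    base_width: int = 128
    input_size: tuple[int, int] = (256, 256)

    def __iter__(self):
        return iter((self.f1, self.f2, self.f3, self.f4))

    def __getitem__(self, i: int) -> Tensor:
        return (self.f1, self.f2, self.f3, self.f4)[i]

    def validate(self) -> None:
        h, w = self.input_size
        c = self.base_width
        for i, f in enumerate(self, start=1):
            expect = (2 ** (i - 1) * c, h // 2 ** (i + 1), w // 2 ** (i + 1))
            if tuple(f.shape[1:]) != expect:
                raise ValueError(f"F{i} has shape {f.shape[1:]}, expected {expect}")


class ConvNextBlock(Module):
    """Depthwise 7x7 -> LayerNorm -> pointwise x4 expansion -> GELU -> pointwise,
    with layer-scale and residual connection."""

    def __init__(self, dim: int, rng: np.random.Generator, layer_scale: float = 1e-6,
                 dtype=np.float32):
        super().__init__()
        self.dwconv = Conv2d(dim, dim, 7, padding=3, groups=dim, rng=rng,
                             dtype=dtype, init="trunc_normal")
        self.norm = LayerNorm2d(dim, dtype=dtype)
        self.pwconv1 = Conv2d(dim, 4 * dim, 1, rng=rng, dtype=dtype, init="trunc_normal")
        self.pwconv2 = Conv2d(4 * dim, dim, 1, rng=rng, dtype=dtype, init="trunc_normal")
        self.gamma = Parameter(np.full((dim, 1, 1), layer_scale, dtype))

    def forward(self, x: Tensor) -> Tensor:
        y = self.dwconv(x)
        y = self.norm(y)
        y = self.pwconv1(y)
        y = F.gelu(y)
        y = self.pwconv2(y)
        return x + y * self.gamma


class ConvNextEncoder(Module):
    def __init__(
        self,
        base_width: int = 128,
        stage_depths: tuple[int, ...] = CONVNEXT_BASE_DEPTHS,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if base_width % 2:
            raise ValueError(f"base_width must be even, got {base_width}")
        if len(stage_depths) != 4:
            raise ValueError(f"stage_depths needs 4 entries, got {len(stage_depths)}")
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        c = base_width
        self.base_width = c
        self.stage_depths = tuple(stage_depths)
        dims = [c, 2 * c, 4 * c, 8 * c]

        self.stem_conv = Conv2d(3, c, 4, stride=4, rng=rng, dtype=dtype,
                                init="trunc_normal")
        self.stem_norm = LayerNorm2d(c, dtype=dtype)
        self.stages = [
            [ConvNextBlock(dims[i], rng, dtype=dtype) for _ in range(stage_depths[i])]
            for i in range(4)
        ]
        self.down_norms = [LayerNorm2d(dims[i], dtype=dtype) for i in range(3)]
        self.down_convs = [
            Conv2d(dims[i], dims[i + 1], 2, stride=2, rng=rng, dtype=dtype,
                   init="trunc_normal")
            for i in range(3)
        ]

    def forward(self, images) -> FeaturePyramid:
        x = as_tensor(images)
        n, ch, h, w = x.shape
        if h % 32:
            raise ValueError(f"input height {h} not divisible by 32")
        if w % 32:
            raise ValueError(f"input width {w} not divisible by 32")
        x = self.stem_norm(self.stem_conv(x))
        feats = []
        for i in range(4):
            if i > 0:
                x = self.down_convs[i - 1](self.down_norms[i - 1](x))
            for block in self.stages[i]:
                x = block(x)
            feats.append(x)
        return FeaturePyramid(*feats, base_width=self.base_width, input_size=(h, w))


def build_convnext_encoder(
    base_width: int = 128,
    stage_depths: tuple[int, ...] = CONVNEXT_BASE_DEPTHS,
    pretrained_weights: str | None = None,
    rng: np.random.Generator | None = None,
    dtype=np.float32,
) -> ConvNextEncoder:
    """Construct the CNN-stream encoder, optionally loading checkpoint weights.

    With a checkpoint path, backbone weights are loaded by name and any
    unmatched keys are reported on the returned encoder as
    ``encoder.load_report``; incompatible shapes raise a ``ValueError`` naming
    the first mismatched tensor.
    """
    enc = ConvNextEncoder(base_width, stage_depths, rng=rng, dtype=dtype)
    if pretrained_weights is not None:
        with np.load(pretrained_weights) as ckpt:
            state = {k: ckpt[k] for k in ckpt.files}
        missing, unexpected = enc.load_state_dict(state, strict=False)
        enc.load_report = {"missing": missing, "unexpected": unexpected}
    return enc


def forward_pyramid(encoder: ConvNextEncoder, images) -> FeaturePyramid:
    """Functional alias for ``encoder(images)``."""
    return encoder(images)
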