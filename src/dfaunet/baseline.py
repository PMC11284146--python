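"""Reference U-Net baseline for ablation comparisons.

A standard 4-down/4-up U-Net: double 3x3 convolutions (bias-free, each
followed by batch norm and ReLU), 2x2 max-pool downsampling, 2x2
transposed-convolution upsampling and a one-channel sigmoid head.  At base
width 64 (doubling to 1024 at the bottleneck) the trainable-parameter count
is 31,037,633 ~= 31.04 M.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, as_tensor, concat
from ._autodiff import functional as F
from ._autodiff.nn import BatchNorm2d, Conv2d, ConvTranspose2d, Module, count_parameters

__all__ = ["UNet", "build_unet_baseline"]


class DoubleConv(Module):
    def __init__(self, in_ch: int, out_ch: int, rng, dtype=np.float32):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, padding=1, bias=False, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(out_ch, dtype=dtype)
        self.conv2 = Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(out_ch, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = F.relu(self.bn1(self.conv1(x)))
        return F.relu(self.bn2(self.conv2(x)))


class UNet(Module):
    def __init__(self, base_width: int = 64, seed: int = 0, dtype=np.float32):
        super().__init__()
        rng = np.random.default_rng(seed)
        w = base_width
        widths = [w, 2 * w, 4 * w, 8 * w, 16 * w]
        self.base_width = w
        self.inc = DoubleConv(3, widths[0], rng, dtype)
        self.downs = [DoubleConv(widths[i], widths[i + 1], rng, dtype) for i in range(4)]
        self.ups = [
            ConvTranspose2d(widths[4 - i], widths[3 - i], 2, rng=rng, dtype=dtype)
            for i in range(4)
        ]
        self.up_convs = [
            DoubleConv(widths[4 - i], widths[3 - i], rng, dtype) for i in range(4)
        ]
        self.out_conv = Conv2d(widths[0], 1, 1, rng=rng, dtype=dtype)
        self.threshold = 0.5

    def forward(self, images):
        x = as_tensor(images)
        skips = [self.inc(x)]
        for down in self.downs:
            skips.append(down(F.max_pool2d(skips[-1], 2)))
        y = skips[-1]
        for up, conv, skip in zip(self.ups, self.up_convs, reversed(skips[:-1])):
            y = conv(concat([skip, up(y)], axis=1))
        return self.out_conv(y)

    def predict_proba(self, images) -> Tensor:
        return F.sigmoid(self.forward(images))

    def predict(self, images) -> np.ndarray:
        was_training = self.training
        self.eval()
        prob = self.predict_proba(images)
        if was_training:
            self.train()
        return (prob.data >= self.threshold).astype(np.uint8)

    def num_parameters(self) -> int:
        return count_parameters(self)


def build_unet_baseline(base_width: int = 64, seed: int = 0) -> UNet:
    """The ablation baseline; at the default width it reproduces 31.04 M params."""
    return UNet(base_width=base_width, seed=seed)
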