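"""Assembly of the dual-stream feature-fusion attention U-Net.

The network segments lesions in pseudo-color ultrasound elastography images:
a ConvNeXt stream extracts a local feature pyramid F1..F4, a lightweight ViT
stream turns F1 into a global feature Fv, the hybrid attention module fuses
Fv with F4 at the bottleneck, and the feature-enhanced residual decoder
recovers a full-resolution binary probability map.

The reference configuration (C=128, ConvNeXt-Base depths, two-conv decoder
stages with hidden width 10*C) totals ~97.29 M trainable parameters; the
width-reduced configuration (C=32) used for CPU-scale experiments keeps the
same topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, as_tensor
from ._autodiff.nn import Module, count_parameters
from .backbone import CONVNEXT_BASE_DEPTHS, ConvNextEncoder, FeaturePyramid
from .decoder import BottleneckFusion, DecoderBlock, SegmentationHead
from .ham import FusedFeature, HybridAttention
from .vit import VitOutput, VitStream

__all__ = ["ModelConfig", "DecoderState", "DFAUNet"]


@dataclass
class ModelConfig:
    base_width: int = 128
    stage_depths: tuple[int, ...] = CONVNEXT_BASE_DEPTHS
    heads: int = 4
    patch_sizes: tuple[int, int] = (4, 16)
    leaky_slope: float = 0.01
    decoder_blocks: int = 2
    decoder_hidden: int | None = None  # default 10 * base_width
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.decoder_hidden is None:
            self.decoder_hidden = 10 * self.base_width


@dataclass
class DecoderState:
    """All intermediates of a forward pass (kept for interpretability maps)."""

    pyramid: FeaturePyramid
    vit: VitOutput
    fused: FusedFeature
    fd_prime: list[Tensor]          # F'd1..F'd4, each C/2 channels
    fo: dict[int, Tensor]           # decoder outputs keyed by stage index 3, 2, 1
    logits: Tensor                  # (N, 1, H, W)
    prob_map: Tensor                # (N, 1, H, W) in [0, 1]
    pred_mask: np.ndarray           # binary uint8 (N, 1, H, W)


class DFAUNet(Module):
    def __init__(self, config: ModelConfig | None = None, dtype=np.float32):
        super().__init__()
        cfg = config or ModelConfig()
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_width
        self.config = cfg
        self.encoder = ConvNextEncoder(c, cfg.stage_depths, rng=rng, dtype=dtype)
        self.vit = VitStream(c, cfg.heads, cfg.patch_sizes, cfg.leaky_slope,
                             rng=rng, dtype=dtype)
        self.ham = HybridAttention(c, rng=rng, dtype=dtype)
        self.fusions = [BottleneckFusion(c, i, rng=rng, dtype=dtype)
                        for i in (1, 2, 3, 4)]
        self.decoders = [
            DecoderBlock(c // 2, cfg.decoder_hidden, cfg.decoder_blocks,
                         cfg.leaky_slope, rng=rng, dtype=dtype)
            for _ in (3, 2, 1)
        ]
        self.head = SegmentationHead(c // 2, rng=rng, dtype=dtype)

    # ------------------------------------------------------------------
    @classmethod
    def reference(cls) -> "DFAUNet":
        """The full-size configuration (C=128)."""
        return cls(ModelConfig())

    @classmethod
    def scaled(cls, base_width: int = 32, seed: int = 0) -> "DFAUNet":
        """A width-reduced configuration with identical topology."""
        return cls(ModelConfig(base_width=base_width, seed=seed))

    # ------------------------------------------------------------------
    def forward(self, images) -> DecoderState:
        x = as_tensor(images)
        n, ch, h, w = x.shape
        pyramid = self.encoder(x)
        vit_out = self.vit(pyramid.f1)
        fused = self.ham(vit_out.fv, pyramid.f4)
        fd_prime = [fusion(fused.fcv, fi) for fusion, fi in zip(self.fusions, pyramid)]
        fo: dict[int, Tensor] = {}
        previous = fd_prime[3]  # F'd4 seeds the chain
        for stage, block in zip((3, 2, 1), self.decoders):
            previous = block(fd_prime[stage - 1], previous)
            fo[stage] = previous
        logits, prob_map, pred_mask = self.head(
            fo[1], (h, w), self.config.threshold
        )
        return DecoderState(
            pyramid=pyramid, vit=vit_out, fused=fused, fd_prime=fd_prime,
            fo=fo, logits=logits, prob_map=prob_map, pred_mask=pred_mask,
        )

    def predict(self, images) -> np.ndarray:
        """Binary masks for a batch, eval mode, no gradient bookkeeping."""
        was_training = self.training
        self.eval()
        state = self.forward(images)
        if was_training:
            self.train()
        return state.pred_mask

    # ------------------------------------------------------------------
    def parameter_breakdown(self) -> dict[str, int]:
        parts = {
            "encoder_cnn": count_parameters(self.encoder),
            "encoder_vit": count_parameters(self.vit),
            "ham": count_parameters(self.ham),
            "frd_fusion": sum(count_parameters(f) for f in self.fusions),
            "frd_decoder": sum(count_parameters(d) for d in self.decoders),
            "head": count_parameters(self.head),
        }
        parts["total"] = sum(v for k, v in parts.items())
        return parts

    def num_parameters(self) -> int:
        return count_parameters(self)
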