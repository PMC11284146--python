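"""Grad-CAM for the decoder stages of the segmentation network.

Adaptation to binary segmentation: the class score is the sum of output
logits over the predicted foreground region.  Its gradient with respect to
a decoder stage's feature map is global-average-pooled per channel to give
channel weights; the heatmap is the ReLU of the channel-weighted sum of
the feature maps, up-sampled to the input resolution and min-max
normalized.  Warm regions mark evidence the model used for the lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from ._autodiff import as_tensor
from ._autodiff import functional as F
from .model import DFAUNet

__all__ = ["CamResult", "grad_cam", "registered_stages"]

# decoder stage label -> key into DecoderState.fo (1 = finest resolution)
_STAGES = {"decoder1": 1, "decoder2": 2, "decoder3": 3}


def registered_stages() -> list[str]:
    return sorted(_STAGES)


@dataclass
class CamResult:
    stage: str
    heatmap: np.ndarray          # (H, W) in [0, 1]
    overlay: np.ndarray          # (H, W, 3) float RGB in [0, 1]
    constant: bool = False       # heatmap was constant before normalization


def _prepare_batch(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 3 and arr.shape[-1] == 3:      # HWC -> 1CHW
        arr = arr.transpose(2, 0, 1)[None]
    elif arr.ndim == 3:                            # CHW
        arr = arr[None]
    elif arr.ndim != 4:
        raise ValueError(f"expected an image of 2-4 dims, got shape {arr.shape}")
    if arr.shape[0] != 1:
        raise ValueError(f"grad_cam works on a single image, got batch {arr.shape[0]}")
    return arr


def grad_cam(model: DFAUNet, image: np.ndarray, stage: str = "decoder1",
             alpha: float = 0.45) -> CamResult:
    """Grad-CAM heatmap of ``stage`` for one image.

    ``stage`` must be one of :func:`registered_stages`; the heatmap and
    overlay are returned at the input resolution.
    """
    if stage not in _STAGES:
        raise ValueError(
            f"unknown stage '{stage}'; registered stages: {registered_stages()}"
        )
    batch = _prepare_batch(image)
    h, w = batch.shape[2], batch.shape[3]

    was_training = model.training
    model.eval()
    state = model.forward(batch)
    if was_training:
        model.train()

    fo = state.fo[_STAGES[stage]]
    # foreground score: sum of logits inside the predicted mask (whole image
    # when the prediction is empty, so the gradient is never all-zero)
    pred = state.pred_mask.astype(np.float32)
    region = pred if pred.any() else np.ones_like(pred)
    score = (state.logits * as_tensor(region)).sum()
    model.zero_grad()
    score.backward()

    grad = fo.grad
    if grad is None:
        raise RuntimeError(f"no gradient reached stage '{stage}'")
    weights = grad.mean(axis=(2, 3), keepdims=True)          # (1, C, 1, 1)
    cam = np.maximum((weights * fo.data).sum(axis=1), 0.0)    # (1, h', w')
    cam_t = F.bilinear_resize(as_tensor(cam[:, None].astype(np.float32)), (h, w))
    heat = cam_t.data[0, 0]

    lo, hi = float(heat.min()), float(heat.max())
    constant = hi - lo <= 1e-12
    heat = np.zeros_like(heat) if constant else (heat - lo) / (hi - lo)

    colored = colormaps["jet"](heat)[..., :3]
    base = batch[0].transpose(1, 2, 0)
    overlay = np.clip((1 - alpha) * base + alpha * colored, 0.0, 1.0)
    return CamResult(stage=stage, heatmap=heat.astype(np.float64),
                     overlay=overlay, constant=constant)
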