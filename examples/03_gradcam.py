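"""Visualise what the network looked at with decoder-stage Grad-CAM.

For binary segmentation the "class score" is the sum of the output logits
over the predicted foreground.  Backpropagating that score to a decoder
stage, pooling the gradient per channel, and taking the ReLU of the
channel-weighted feature sum gives a heatmap of the evidence the model
used.  A well-behaved model concentrates the heat inside the lesion.

Run:  python examples/03_gradcam.py         (~3 minutes on 1 CPU)
"""

import numpy as np

from dfaunet import SynthConfig, TrainConfig, generate_synthetic_dataset, train
from dfaunet.gradcam import grad_cam, registered_stages
from dfaunet.model import DFAUNet, ModelConfig

# 1. A quick small-scale training run (same recipe as example 02).
samples = generate_synthetic_dataset(SynthConfig(n_images=36, image_size=64, seed=3))
train_set, test_set = samples[:28], samples[28:]
model = DFAUNet(ModelConfig(base_width=16, decoder_hidden=32, seed=0))
train(model, train_set, TrainConfig(lr=1e-3, epochs=6, lr_step=6,
                                    batch_size=4, seed=0),
      val_samples=test_set)

# 2. Heatmaps at every registered decoder stage for one test image.
sample = test_set[0]
print(f"stages: {registered_stages()}")
results = {stage: grad_cam(model, sample.image, stage)
           for stage in registered_stages()}

# 3. The localisation statistic used by the acceptance checks: is the mean
#    normalised heat inside the true lesion larger than outside?
for stage, res in results.items():
    inside = sample.mask.astype(bool)
    print(f"  {stage}: heat inside {res.heatmap[inside].mean():.3f} "
          f"vs outside {res.heatmap[~inside].mean():.3f}"
          + ("  [constant map]" if res.constant else ""))

# 4. Save the overlays.
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

fig, axes = plt.subplots(1, 5, figsize=(15, 3.2))
axes[0].imshow(sample.image)
axes[0].set_title("input")
axes[1].imshow(sample.mask, cmap="gray")
axes[1].set_title("truth")
for ax, (stage, res) in zip(axes[2:], results.items()):
    ax.imshow(res.overlay)
    ax.set_title(stage)
for ax in axes:
    ax.axis("off")
fig.tight_layout()
fig.savefig("gradcam_overlays.png", dpi=110)
print("wrote gradcam_overlays.png")
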