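"""Generate a synthetic elastography dataset and inspect it.

Pseudo-color ultrasound elastography maps tissue stiffness to color: soft
tissue renders green, stiff (suspicious) tissue renders blue, and a red/
yellow fringe appears around compression artefacts.  The synthetic
generator builds one lesion ("node") per image: a smooth Fourier-perturbed
ellipse whose interior mixes blue-dominant and green-dominant regions in a
configurable ratio, composited over a green/red background with speckle
noise — enough structure for a segmentation network to need both local
texture and global shape.

Run:  python examples/01_synthetic_data.py
"""

import numpy as np

from dfaunet import SynthConfig, generate_synthetic_dataset, make_fold_plan

# 1. Generate a small dataset.  Everything is deterministic in the seed and
#    each sample depends only on (seed, index), so datasets are stable under
#    resizing of n_images.
cfg = SynthConfig(n_images=24, image_size=128, hardness_mix=0.55, seed=7)
samples = generate_synthetic_dataset(cfg)

print(f"generated {len(samples)} samples of {cfg.image_size}x{cfg.image_size}")
labels = [s.label for s in samples]
print(f"labels: {labels.count('malignant')} malignant / "
      f"{labels.count('benign')} benign")

# 2. Check the stiffness mix: the fraction of blue-dominant pixels inside
#    each node should sit near the configured hardness_mix on average.
fracs = []
for s in samples:
    inside = s.image[s.mask.astype(bool)]
    fracs.append((inside[:, 2] > inside[:, 1]).mean())
print(f"mean interior blue fraction: {np.mean(fracs):.3f} "
      f"(target {cfg.hardness_mix})")

# 3. Build the six-fold cross-validation plan used throughout the package.
plan = make_fold_plan([s.image_id for s in samples], k=6, seed=0)
print(f"fold sizes: {plan.fold_sizes()}")
print(f"fold 0: {len(plan.train_ids(0))} train / {len(plan.test_ids(0))} test")

# 4. Save a montage for visual inspection (images on top, masks below).
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

fig, axes = plt.subplots(2, 6, figsize=(14, 5))
for col, s in enumerate(samples[:6]):
    axes[0, col].imshow(s.image)
    axes[0, col].set_title(s.label, fontsize=9)
    axes[1, col].imshow(s.mask, cmap="gray")
    for row in (0, 1):
        axes[row, col].axis("off")
fig.tight_layout()
fig.savefig("synthetic_montage.png", dpi=110)
print("wrote synthetic_montage.png")
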