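# Methods and design rationale

This note explains the engineering decisions behind the package: why each
piece is built the way it is, what was deliberately scaled down for a
single-CPU budget, and how the numerical core is verified.

## 1. A NumPy autodiff engine instead of a framework

The target environment provides scientific Python but no deep-learning
framework, so the package ships a compact reverse-mode autodiff engine
(`dfaunet._autodiff`): a `Tensor` with a closure-based backward graph,
a module system with named parameters/buffers and state-dict round trips,
`Adam` with decoupled weight decay, and a step scheduler.

Every differentiable operation is covered by central finite-difference
gradient checks (`tests/test_autodiff.py`), which proved essential when
optimising the hot paths:

* **Convolutions** use a channel-first im2col layout
  `(N, C·kh·kw, Ho·Wo)` so the forward pass is a single batched matmul
  producing NCHW directly; the weight gradient is the transposed batched
  matmul, and the stride-1 input gradient is a correlation with the
  flipped kernel. Strided input gradients scatter through a col2im
  adjoint.
* **Depthwise 7×7** (the ConvNeXt spatial mixer) and the elementwise
  bottlenecks (GELU backward, leaky ReLU, batch-norm) have optional
  **numba** kernels. numba is a hard dependency of the package metadata
  but a soft dependency at runtime: every kernel has a pure-NumPy
  fallback selected at import, so the library degrades gracefully.
* GELU's forward stays in NumPy: `x³` is computed as `x·x·x` (NumPy's
  float32 `power` is ~80× slower than chained multiplies and dominated
  early profiles).

With these, a training step of the benchmark model (batch 8, 128² images)
takes well under a second on one CPU core.

## 2. Architecture contracts

The model code is organised around explicit, testable contracts:

* `FeaturePyramid.validate()` pins the scale/width contract
  `Fi: (2^(i-1)·C, H/2^(i+1), W/2^(i+1))`.
* The ViT stream asserts `Fv` keeps exactly F1's shape and that
  `Fv = F1 + F_MHA + F_FF` holds as a tensor identity.
* Channel attention is parameter-free and its mixing matrix is
  row-stochastic by construction; both facts are asserted against
  hand-computed oracles.
* The decoder stage reduces to its two residual paths when the conv
  branch is silenced — the "residual identity" test — which pins the
  three-branch wiring.
* Parameter anchors: ConvNeXt-Base trunk 87,564,416; U-Net baseline
  31,037,633; assembled model 97,295,749. These are computed, not stored:
  the tests rebuild the models and count.

The per-module breakdown (`DFAUNet.parameter_breakdown`) exists so a
mismatch is attributable to a specific module rather than a diff of one
large number.

## 3. Synthetic elastography data

Clinical elastography data is not redistributable, so the data module
synthesises images with the properties the architecture is designed to
exploit:

* a single node per image: an ellipse with low-order Fourier boundary
  perturbation (global shape, irregular margin);
* an interior stiffness mix: a smooth random field thresholded at an
  empirical quantile so the blue-dominant fraction matches the configured
  `hardness_mix` exactly per sample (plus small noise), which also drives
  the benign/malignant label;
* green/red background fields, Gaussian-blurred alpha compositing at the
  node boundary, and multiplicative speckle.

Determinism is structural: sample `i` uses `default_rng([seed, i])`, so
datasets are reproducible and stable under changes of `n_images`.

## 4. Training protocol

`TrainConfig` defaults encode the full-scale recipe (Adam lr 1e-4, weight
decay 0.1 applied in decoupled form, Dice loss, batch 8, 190 epochs, 10×
lr decay every 90 epochs, flip/±30° augmentation, best-val-Dice
checkpointing). The loop is deterministic given the seed (per-epoch
`default_rng([seed, epoch])` drives shuffling and augmentation), and a
non-finite loss aborts cleanly: the best checkpoint is restored and a
diagnostic recorded rather than propagating NaNs.

## 5. The CPU-scale benchmark

The published accuracies (mean Dice ≈ 0.93 on 263 clinical images) cannot
be reproduced without the private dataset and GPU-scale training. The
substitute claim was fixed *before* any benchmark outcome was observed:

* width-reduced model `C=32`, decoder hidden 64 (the full `10·C` decoder
  hidden is the dominant cost at small widths and is not needed at this
  scale);
* 64 train / 16 test synthetic 128² images (`data_seed=11`), 30 epochs,
  batch 8, lr 1e-3 (a short-schedule rate; no decay within 30 epochs);
* three seeds (0, 1, 2) averaged for the dual-stream model, one run for
  the width-16 U-Net baseline;
* acceptance thresholds: mean test Dice ≥ 0.80, and the dual-stream model
  within 0.02 Dice of the baseline.

Each run takes a few minutes on one CPU; the whole benchmark fits the
acceptance budget with margin. The thresholds are deliberately loose:
they certify "the architecture trains and segments", not a leaderboard
number.

## 6. Metrics

Overlap metrics come from exact confusion counts with a defined-empty
convention (0/0 → 1, flagged `degenerate`). HD95 is the symmetric 95th
percentile (linear interpolation) of boundary-to-boundary nearest-
neighbour distances; boundaries are erosion differences with the 3×3
cross. A brute-force all-pairs backend and a full-foreground variant
exist purely as cross-checks, and empty masks yield `None` (undefined)
rather than a sentinel number — aggregation counts them explicitly.

## 7. Grad-CAM for segmentation

Classification Grad-CAM needs a scalar class score; for binary
segmentation the score is the sum of output logits over the predicted
foreground (falling back to the whole image when the prediction is empty
so the gradient never vanishes identically). Heatmaps are available for
all three decoder stages; the finest (`decoder1`) is the default and the
one used by the localisation check, with constant heatmaps flagged
instead of silently normalised.
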