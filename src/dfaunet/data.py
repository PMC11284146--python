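"""Synthetic pseudo-color elastography data, fold bookkeeping, augmentation, I/O.

Elastography renders tissue stiffness as color: soft tissue appears green,
stiff tissue blue, and mixed regions reddish-green/reddish-blue.  The
synthetic generator emulates that appearance so the pipeline can be
exercised end-to-end without clinical data: each sample is one smooth
random blob (a Fourier-perturbed ellipse) whose interior mixes blue-dominant
and green-dominant texture in a configurable ratio (``hardness_mix``), on a
green/red background, with Gaussian boundary blur and multiplicative
speckle.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, rotate as nd_rotate
from skimage.transform import resize as sk_resize

__all__ = [
    "Sample",
    "FoldPlan",
    "SynthConfig",
    "generate_synthetic_dataset",
    "make_fold_plan",
    "augment",
    "load_dataset",
    "resize_to",
    "save_dataset",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class Sample:
    """One image/mask pair.  ``image`` is (H, W, 3) float in [0,1];
    ``mask`` is (H, W) uint8 in {0,1}."""

    image_id: str
    image: np.ndarray
    mask: np.ndarray
    label: str = "benign"

    def validate(self) -> "Sample":
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"{self.image_id}: image {self.image.shape[:2]} vs "
                f"mask {self.mask.shape} spatial shapes differ"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{self.image_id}: mask values {vals[:8]} not in {{0,1}}")
        return self


@dataclass
class FoldPlan:
    """Assignment of every image id to one of ``k`` near-equal folds."""

    n_samples: int
    fold_of: dict[str, int]
    test_fold: int
    seed: int

    @property
    def k(self) -> int:
        return max(self.fold_of.values()) + 1

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.fold_of.values():
            sizes[f] += 1
        return sizes

    def test_ids(self, test_fold: int | None = None) -> list[str]:
        tf = self.test_fold if test_fold is None else test_fold
        return sorted(i for i, f in self.fold_of.items() if f == tf)

    def train_ids(self, test_fold: int | None = None) -> list[str]:
        tf = self.test_fold if test_fold is None else test_fold
        return sorted(i for i, f in self.fold_of.items() if f != tf)


@dataclass
class SynthConfig:
    n_images: int = 263
    image_size: int = 256
    node_radius_range: tuple[float, float] = (0.18, 0.34)  # fraction of size
    boundary_blur_sigma: float = 1.5
    speckle_strength: float = 0.15
    hardness_mix: float = 0.55
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.node_radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"node_radius_range must be positive, got {self.node_radius_range}")
        if hi >= 0.5:
            raise ValueError(
                f"node radius {hi} (fraction of image size) must stay below 0.5 "
                "so the node fits in the image"
            )
        if not 0 <= self.speckle_strength < 1:
            raise ValueError(f"speckle_strength must be in [0,1), got {self.speckle_strength}")
        if not 0 <= self.hardness_mix <= 1:
            raise ValueError(f"hardness_mix must be in [0,1], got {self.hardness_mix}")
        if self.n_images < 1 or self.image_size < 16:
            raise ValueError("need n_images >= 1 and image_size >= 16")


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Low-pass-filtered white noise, rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal((size, size)), sigma)
    f -= f.min()
    span = f.max()
    return f / span if span > 0 else f


def _blob_mask(rng: np.random.Generator, size: int,
               radius_range: tuple[float, float]) -> np.ndarray:
    """Fourier-perturbed ellipse rasterized as a binary mask."""
    r0 = rng.uniform(*radius_range) * size
    cx = size / 2 + rng.uniform(-0.08, 0.08) * size
    cy = size / 2 + rng.uniform(-0.08, 0.08) * size
    aspect = rng.uniform(0.7, 1.4)
    tilt = rng.uniform(0, np.pi)
    n_harm = 5
    amps = rng.uniform(0, 0.09, n_harm) / np.arange(1, n_harm + 1)
    phases = rng.uniform(0, 2 * np.pi, n_harm)

    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    # rotate into the ellipse frame, squeeze one axis
    ex = dx * np.cos(tilt) + dy * np.sin(tilt)
    ey = (-dx * np.sin(tilt) + dy * np.cos(tilt)) * aspect
    rr = np.hypot(ex, ey)
    theta = np.arctan2(ey, ex)
    boundary = r0 * (1 + sum(
        a * np.cos((k + 1) * theta + ph)
        for k, (a, ph) in enumerate(zip(amps, phases))
    ))
    return (rr <= boundary).astype(np.uint8)


def _render_sample(rng: np.random.Generator, cfg: SynthConfig,
                   image_id: str) -> Sample:
    size = cfg.image_size
    mask = _blob_mask(rng, size, cfg.node_radius_range)
    while mask.sum() < 16:  # degenerate draw; resample deterministically
        mask = _blob_mask(rng, size, cfg.node_radius_range)

    # per-sample stiffness ratio with a little spread around the configured mix
    blue_frac = float(np.clip(cfg.hardness_mix + rng.normal(0, 0.03), 0.02, 0.98))

    # interior: blue- vs green-dominant regions from a smooth field whose
    # empirical quantile fixes the blue fraction exactly (before blur/speckle)
    interior_field = _smooth_field(rng, size, sigma=size / 16)
    inside_vals = interior_field[mask == 1]
    thresh = float(np.quantile(inside_vals, 1.0 - blue_frac))
    blue_region = (interior_field >= thresh).astype(float)

    # pseudo-color palettes (soft = green, stiff = blue, background = green/red)
    interior = np.empty((size, size, 3))
    interior[..., 0] = 0.15 + 0.1 * interior_field          # faint red
    interior[..., 1] = np.where(blue_region, 0.25, 0.75)     # green for soft
    interior[..., 2] = np.where(blue_region, 0.85, 0.30)     # blue for stiff

    bg_field = _smooth_field(rng, size, sigma=size / 10)
    background = np.empty((size, size, 3))
    background[..., 0] = 0.30 + 0.45 * bg_field              # reddish patches
    background[..., 1] = 0.65 - 0.35 * bg_field              # green elsewhere
    background[..., 2] = 0.12 + 0.08 * (1 - bg_field)

    alpha = gaussian_filter(mask.astype(float), cfg.boundary_blur_sigma)
    image = alpha[..., None] * interior + (1 - alpha[..., None]) * background
    if cfg.speckle_strength > 0:
        speckle = 1 + cfg.speckle_strength * rng.standard_normal((size, size, 1))
        image = image * speckle
    image = np.clip(image, 0.0, 1.0)

    label = "malignant" if blue_frac >= cfg.hardness_mix else "benign"
    return Sample(image_id=image_id, image=image.astype(np.float32),
                  mask=mask, label=label)


def generate_synthetic_dataset(cfg: SynthConfig) -> list[Sample]:
    """Deterministic synthetic dataset; sample ``i`` is seeded by (seed, i)."""
    samples = []
    for i in range(cfg.n_images):
        rng = np.random.default_rng([cfg.seed, i])
        samples.append(_render_sample(rng, cfg, f"synth{i:04d}").validate())
    return samples


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_fold_plan(ids: int | Sequence[str], k: int = 6, seed: int = 0,
                   test_fold: int = 0) -> FoldPlan:
    """Random permutation split of ``ids`` into ``k`` near-equal folds.

    ``ids`` may be an integer n (generic ids are generated) or a sequence of
    image ids.  Fold sizes differ by at most one; with n=263 and k=6 the
    sizes are five folds of 44 and one of 43, giving a 219/44 train/test
    split whenever a 44-sized fold is held out.
    """
    if isinstance(ids, (int, np.integer)):
        id_list = [f"img{i:04d}" for i in range(int(ids))]
    else:
        id_list = list(ids)
        if len(set(id_list)) != len(id_list):
            raise ValueError("image ids must be unique")
    n = len(id_list)
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    if not 0 <= test_fold < k:
        raise ValueError(f"test_fold must be in [0, {k}), got {test_fold}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    # contiguous chunks of the permutation; the first (n mod k) folds get the
    # extra sample, so fold sizes differ by at most one
    base, extra = divmod(n, k)
    fold_of: dict[str, int] = {}
    pos = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        for idx in order[pos:pos + size]:
            fold_of[id_list[idx]] = f
        pos += size
    return FoldPlan(n_samples=n, fold_of=fold_of, test_fold=test_fold, seed=seed)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(sample: Sample, p: float = 0.5,
            angle_choices: Sequence[float] = (-30.0, 30.0),
            rng: np.random.Generator | None = None,
            uniform_range: bool = False) -> Sample:
    """Online augmentation: vertical flip and a rotation, each applied with
    probability ``p`` (independent coins), identically to image and mask.

    The rotation angle is drawn from ``angle_choices`` (the default reads
    "-30 or +30" literally); with ``uniform_range`` it is instead uniform in
    [min, max] of the choices.  Rotation fills with 0 (black background) and
    uses bilinear interpolation for the image, nearest for the mask.
    """
    rng = rng or np.random.default_rng(0)
    image, mask = sample.image, sample.mask
    if rng.random() < p:
        image = image[::-1].copy()
        mask = mask[::-1].copy()
    if rng.random() < p:
        if uniform_range:
            angle = float(rng.uniform(min(angle_choices), max(angle_choices)))
        else:
            angle = float(rng.choice(np.asarray(angle_choices, dtype=float)))
        image = nd_rotate(image, angle, axes=(1, 0), reshape=False,
                          order=1, mode="constant", cval=0.0)
        image = np.clip(image, 0.0, 1.0)
        mask = nd_rotate(mask, angle, axes=(1, 0), reshape=False,
                         order=0, mode="constant", cval=0)
    return replace(sample, image=np.ascontiguousarray(image, dtype=np.float32),
                   mask=np.ascontiguousarray(mask, dtype=np.uint8)).validate()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_IMAGE_EXTS = (".png", ".jpg", ".jpeg")


def resize_to(sample: Sample, size: int = 256) -> Sample:
    """Bilinear-resize the image and nearest-resize (re-binarized) the mask."""
    image = sk_resize(sample.image, (size, size), order=1, mode="reflect",
                      anti_aliasing=True, preserve_range=True)
    mask = sk_resize(sample.mask.astype(float), (size, size), order=0,
                     mode="constant", anti_aliasing=False, preserve_range=True)
    return replace(
        sample,
        image=np.clip(image, 0.0, 1.0).astype(np.float32),
        mask=(mask >= 0.5).astype(np.uint8),
    ).validate()


def _read_image(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 2:                       # grayscale -> replicated RGB
        arr = np.repeat(arr[..., None], 3, axis=2)
    if arr.shape[2] == 4:                   # drop alpha
        arr = arr[..., :3]
    return (arr.astype(np.float32) / 255.0).clip(0.0, 1.0)


def _read_mask(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= 128).astype(np.uint8)


def load_dataset(image_dir, mask_dir) -> tuple[list[Sample], list[str]]:
    """Load image/mask pairs matched by file stem.

    Returns (samples, errors); an image without a matching mask is skipped
    and reported in ``errors``.
    """
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    masks = {p.stem: p for p in sorted(mask_dir.iterdir())
             if p.suffix.lower() in _IMAGE_EXTS} if mask_dir.is_dir() else {}
    samples, errors = [], []
    for img_path in sorted(image_dir.iterdir()):
        if img_path.suffix.lower() not in _IMAGE_EXTS:
            continue
        mask_path = masks.get(img_path.stem)
        if mask_path is None:
            errors.append(f"{img_path.name}: no mask named '{img_path.stem}.*' "
                          f"in {mask_dir}")
            continue
        samples.append(Sample(
            image_id=img_path.stem,
            image=_read_image(img_path),
            mask=_read_mask(mask_path),
        ).validate())
    return samples, errors


def save_dataset(samples: Iterable[Sample], out_dir,
                 fold_plan: FoldPlan | None = None) -> Path:
    """Write PNG images/masks plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    msk_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    msk_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "image_path", "mask_path", "label", "fold"])
        for s in samples:
            ip = img_dir / f"{s.image_id}.png"
            mp = msk_dir / f"{s.image_id}.png"
            Image.fromarray((s.image * 255).round().astype(np.uint8)).save(ip)
            Image.fromarray((s.mask * 255).astype(np.uint8)).save(mp)
            fold = fold_plan.fold_of.get(s.image_id, "") if fold_plan else ""
            writer.writerow([s.image_id, str(ip), str(mp), s.label, fold])
    return manifest
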