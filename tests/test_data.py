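"""Tests for synthetic data, fold plans, augmentation and dataset I/O."""

import numpy as np
import pytest

from dfaunet.data import (FoldPlan, Sample, SynthConfig, augment,
                          generate_synthetic_dataset, load_dataset,
                          make_fold_plan, resize_to, save_dataset)


# ---------------------------------------------------------------------------
# synthetic generation
# ---------------------------------------------------------------------------

class TestSynth:
    def test_samples_are_valid_and_nonempty(self, tiny_samples):
        for s in tiny_samples:
            assert s.image.shape == (64, 64, 3)
            assert s.image.dtype == np.float32
            assert 0.0 <= s.image.min() and s.image.max() <= 1.0
            assert set(np.unique(s.mask)) <= {0, 1}
            assert s.mask.sum() >= 16
            assert s.label in ("benign", "malignant")

    def test_generation_is_deterministic(self):
        cfg = SynthConfig(n_images=3, image_size=64, seed=9)
        a = generate_synthetic_dataset(cfg)
        b = generate_synthetic_dataset(cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.image, sb.image)
            np.testing.assert_array_equal(sa.mask, sb.mask)
            assert sa.image_id == sb.image_id

    def test_samples_are_per_index_independent(self):
        """Sample i must not depend on how many samples precede it."""
        long = generate_synthetic_dataset(SynthConfig(n_images=5, image_size=64, seed=4))
        short = generate_synthetic_dataset(SynthConfig(n_images=3, image_size=64, seed=4))
        np.testing.assert_array_equal(long[2].image, short[2].image)

    def test_interior_blue_fraction_tracks_hardness_mix(self):
        """Averaged over many nodes the blue (stiff) interior share must sit
        near the configured mix."""
        cfg = SynthConfig(n_images=100, image_size=64, hardness_mix=0.55, seed=3)
        samples = generate_synthetic_dataset(cfg)
        fracs = []
        for s in samples:
            inside = s.image[s.mask.astype(bool)]
            blue = (inside[:, 2] > inside[:, 1]).mean()
            fracs.append(blue)
        assert abs(np.mean(fracs) - 0.55) < 0.1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SynthConfig(node_radius_range=(-0.1, 0.2))
        with pytest.raises(ValueError):
            SynthConfig(node_radius_range=(0.2, 0.6))
        with pytest.raises(ValueError):
            SynthConfig(speckle_strength=1.5)
        with pytest.raises(ValueError):
            SynthConfig(hardness_mix=1.2)
        with pytest.raises(ValueError):
            SynthConfig(n_images=0)

    def test_sample_validate_catches_corruption(self, tiny_samples):
        s = tiny_samples[0]
        bad = Sample(s.image_id, s.image, s.mask[:32], s.label)
        with pytest.raises(ValueError):
            bad.validate()
        bad2 = Sample(s.image_id, s.image, s.mask * 3, s.label)
        with pytest.raises(ValueError, match="not in"):
            bad2.validate()


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

class TestFoldPlan:
    def test_263_samples_split_219_44(self):
        plan = make_fold_plan(263, k=6, seed=0)
        assert plan.k == 6
        assert sorted(plan.fold_sizes()) == [43, 44, 44, 44, 44, 44]
        assert len(plan.test_ids()) in (43, 44)
        assert len(plan.test_ids(0)) + len(plan.train_ids(0)) == 263
        # the canonical test fold of size 44 leaves 219 for training
        sizes = {f: plan.fold_sizes()[f] for f in range(6)}
        f44 = next(f for f, n in sizes.items() if n == 44)
        assert len(plan.train_ids(f44)) == 219

    def test_folds_partition_the_ids(self):
        plan = make_fold_plan(20, k=6, seed=1)
        all_ids = set()
        for f in range(plan.k):
            ids = set(plan.test_ids(f))
            assert ids.isdisjoint(all_ids)
            all_ids |= ids
        assert len(all_ids) == 20

    def test_train_and_test_are_complementary(self):
        plan = make_fold_plan(13, k=4, seed=2)
        for f in range(4):
            assert set(plan.test_ids(f)) | set(plan.train_ids(f)) == set(plan.fold_of)
            assert not set(plan.test_ids(f)) & set(plan.train_ids(f))

    def test_seed_changes_assignment(self):
        p1 = make_fold_plan(30, k=6, seed=0)
        p2 = make_fold_plan(30, k=6, seed=1)
        assert p1.fold_of != p2.fold_of
        assert make_fold_plan(30, k=6, seed=0).fold_of == p1.fold_of

    def test_errors(self):
        with pytest.raises(ValueError, match="cannot split"):
            make_fold_plan(3, k=6)
        with pytest.raises(ValueError, match="unique"):
            make_fold_plan(["a", "a", "b", "c", "d", "e"], k=2)
        with pytest.raises(ValueError, match="test_fold"):
            make_fold_plan(12, k=6, test_fold=6)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

class TestAugment:
    def test_p_zero_is_identity(self, tiny_samples):
        s = tiny_samples[0]
        out = augment(s, p=0.0, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out.image, s.image)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_flip_is_an_involution(self, tiny_samples):
        s = tiny_samples[1]
        # p=1 with no rotation: force the deterministic flip branch
        once = augment(s, p=1.0, angle_choices=(0.0,), rng=np.random.default_rng(0))
        twice = augment(once, p=1.0, angle_choices=(0.0,), rng=np.random.default_rng(0))
        np.testing.assert_allclose(twice.image, s.image, atol=1e-6)
        np.testing.assert_array_equal(twice.mask, s.mask)

    def test_outputs_stay_valid(self, tiny_samples):
        rng = np.random.default_rng(5)
        for s in tiny_samples:
            out = augment(s, p=0.7, rng=rng)
            out.validate()
            assert out.image.min() >= 0 and out.image.max() <= 1

    def test_mask_follows_image(self, tiny_samples):
        """After a rotation the mask must still cover the rendered node."""
        s = tiny_samples[2]
        out = augment(s, p=1.0, rng=np.random.default_rng(8))
        node = out.image[:, :, 2] > out.image[:, :, 0]  # blue/green over red
        inter = (node & out.mask.astype(bool)).sum()
        union = (node | out.mask.astype(bool)).sum()
        assert inter / union > 0.5  # coarse but rotation-sensitive alignment

    def test_area_roughly_preserved(self, tiny_samples):
        rng = np.random.default_rng(3)
        for s in tiny_samples:
            out = augment(s, p=1.0, rng=rng)
            rel = abs(int(out.mask.sum()) - int(s.mask.sum())) / s.mask.sum()
            assert rel < 0.1


# ---------------------------------------------------------------------------
# I/O and resizing
# ---------------------------------------------------------------------------

class TestIO:
    def test_save_load_roundtrip(self, tiny_samples, tmp_path):
        plan = make_fold_plan([s.image_id for s in tiny_samples], k=2, seed=0)
        manifest = save_dataset(tiny_samples, tmp_path / "ds", plan)
        assert manifest.is_file()
        samples, errors = load_dataset(tmp_path / "ds" / "images",
                                       tmp_path / "ds" / "masks")
        assert errors == []
        assert len(samples) == len(tiny_samples)
        by_id = {s.image_id: s for s in samples}
        for orig in tiny_samples:
            got = by_id[orig.image_id]
            np.testing.assert_array_equal(got.mask, orig.mask)
            # 8-bit quantisation on the image channel values
            assert np.abs(got.image - orig.image).max() <= 1 / 255 + 1e-6

    def test_missing_mask_is_reported_not_fatal(self, tiny_samples, tmp_path):
        save_dataset(tiny_samples[:2], tmp_path / "ds")
        extra = tmp_path / "ds" / "images" / "orphan.png"
        extra.write_bytes((tmp_path / "ds" / "images" /
                           f"{tiny_samples[0].image_id}.png").read_bytes())
        samples, errors = load_dataset(tmp_path / "ds" / "images",
                                       tmp_path / "ds" / "masks")
        assert len(samples) == 2
        assert len(errors) == 1 and "orphan" in errors[0]

    def test_grayscale_is_promoted(self, tmp_path):
        from PIL import Image
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        Image.fromarray(np.full((32, 32), 128, np.uint8), "L").save(
            tmp_path / "images" / "g.png")
        mask = np.zeros((32, 32), np.uint8)
        mask[10:20, 10:20] = 255
        Image.fromarray(mask, "L").save(tmp_path / "masks" / "g.png")
        samples, errors = load_dataset(tmp_path / "images", tmp_path / "masks")
        assert errors == []
        assert samples[0].image.shape == (32, 32, 3)
        assert samples[0].mask.sum() == 100

    def test_resize_rebinarises_mask(self, tiny_samples):
        out = resize_to(tiny_samples[0], 32)
        assert out.image.shape == (32, 32, 3)
        assert set(np.unique(out.mask)) <= {0, 1}
        out.validate()
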