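"""Tests for the training loop, evaluation and cross-validation."""

import numpy as np
import pytest

from dfaunet.baseline import UNet
from dfaunet.data import Sample
from dfaunet.train import (TrainConfig, build_model, cross_validate, evaluate,
                           train)


def _small_cfg(**kw):
    defaults = dict(lr=3e-3, epochs=4, batch_size=4, seed=0, augment=False)
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="module")
def smoke_result(tiny_samples):
    """One shared short training run on the shared 64x64 samples."""
    model = UNet(base_width=8, seed=0)
    result = train(model, tiny_samples[:6], _small_cfg(),
                   val_samples=tiny_samples[6:])
    return model, result


class TestTrainLoop:
    def test_loss_decreases(self, smoke_result):
        _, result = smoke_result
        losses = [r["train_loss"] for r in result.history]
        assert len(losses) == 4
        assert losses[-1] < losses[0]

    def test_history_records_lr_schedule(self, tiny_samples):
        model = UNet(base_width=8, seed=1)
        cfg = _small_cfg(epochs=4, lr=1e-3, lr_step=2, lr_gamma=0.1)
        result = train(model, tiny_samples[:4], cfg)
        lrs = [r["lr"] for r in result.history]
        assert lrs == pytest.approx([1e-3, 1e-3, 1e-4, 1e-4])

    def test_best_checkpoint_is_restored(self, smoke_result):
        model, result = smoke_result
        assert result.best_epoch >= 0
        assert result.best_val_dice == max(r["val_dice"] for r in result.history)
        best = result.best_state
        for name, arr in model.state_dict().items():
            np.testing.assert_array_equal(arr, best[name])

    def test_training_is_deterministic(self, tiny_samples):
        runs = []
        for _ in range(2):
            model = UNet(base_width=8, seed=3)
            result = train(model, tiny_samples[:4], _small_cfg(epochs=2, seed=5))
            runs.append([r["train_loss"] for r in result.history])
        assert runs[0] == runs[1]

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_nan_abort_restores_and_diagnoses(self, tiny_samples):
        model = UNet(base_width=8, seed=0)
        # an absurd learning rate reliably blows the loss up to non-finite
        result = train(model, tiny_samples[:4], _small_cfg(lr=1e6, epochs=6))
        assert result.aborted
        assert "non-finite" in result.diagnostic
        assert np.isfinite(
            float(model(np.stack([tiny_samples[0].image.transpose(2, 0, 1)])).data.sum())
        )

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(UNet(base_width=8), [], _small_cfg())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(lr=-1)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(device="cuda")


class _TruthOracle:
    """Test double that predicts exactly the ground truth it was given."""

    def __init__(self, samples):
        self._by_image = {s.image.tobytes(): s.mask for s in samples}
        self.training = False

    def eval(self):
        return self

    def train(self):
        return self

    def predict(self, images):
        masks = [self._by_image[np.ascontiguousarray(
            img.transpose(1, 2, 0)).tobytes()] for img in images]
        return np.stack(masks)[:, None].astype(np.uint8)


class _ZeroPredictor:
    training = False

    def eval(self):
        return self

    def train(self):
        return self

    def predict(self, images):
        return np.zeros((images.shape[0], 1) + images.shape[2:], np.uint8)


class TestEvaluate:
    def test_perfect_predictor_scores_one(self, tiny_samples):
        report = evaluate(_TruthOracle(tiny_samples), tiny_samples)
        agg = report.aggregate()
        assert agg["dice_mean"] == pytest.approx(1.0)
        assert agg["hd95_mean"] == pytest.approx(0.0)
        assert agg["hd95_undefined_count"] == 0

    def test_zero_predictor_scores_zero(self, tiny_samples):
        agg = evaluate(_ZeroPredictor(), tiny_samples).aggregate()
        assert agg["dice_mean"] == pytest.approx(0.0)
        # empty predictions leave HD95 undefined on every image
        assert agg["hd95_undefined_count"] == len(tiny_samples)

    def test_empty_set_rejected(self, tiny_samples):
        with pytest.raises(ValueError, match="empty"):
            evaluate(_ZeroPredictor(), [])


class TestCrossValidate:
    def test_bookkeeping_and_pooling(self, tiny_samples):
        built = []

        def factory(fold):
            built.append(fold)
            return UNet(base_width=8, seed=fold)

        out = cross_validate(factory, list(tiny_samples),
                             _small_cfg(epochs=1), k=2, fold_seed=0)
        assert built == [0, 1]
        assert len(out["folds"]) == 2
        assert out["plan"].k == 2
        for key, val in out["pooled"].items():
            assert key.endswith("_mean")
            per_fold = [f[key] for f in out["folds"] if key in f]
            assert val == pytest.approx(np.mean(per_fold))

    def test_k_larger_than_dataset_rejected(self, tiny_samples):
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(lambda f: UNet(8), list(tiny_samples[:3]),
                           _small_cfg(), k=6)


class TestBuildModel:
    def test_kinds(self):
        from dfaunet.model import DFAUNet

        assert isinstance(build_model("dfa-unet", base_width=16,
                                      decoder_hidden=32), DFAUNet)
        assert isinstance(build_model("dfa_unet", base_width=16,
                                      decoder_hidden=32), DFAUNet)
        assert isinstance(build_model("unet", base_width=8), UNet)
        with pytest.raises(ValueError, match="unknown model kind"):
            build_model("transformer")
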