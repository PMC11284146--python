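"""Tests for the loss and metric suite: hand-worked oracles and properties."""

import json

import numpy as np
import pytest

from dfaunet._autodiff import as_tensor
from dfaunet.metrics import (ConfusionSets, MetricsReport, boundary_points,
                             confusion_counts, dice_loss, hd95,
                             overlap_metrics)


def _mask(shape, coords):
    m = np.zeros(shape, dtype=np.uint8)
    for r, c in coords:
        m[r, c] = 1
    return m


# ---------------------------------------------------------------------------
# Dice loss
# ---------------------------------------------------------------------------

class TestDiceLoss:
    def test_perfect_prediction_is_zero(self):
        t = _mask((4, 4), [(1, 1), (1, 2)])
        assert float(dice_loss(t.astype(np.float64), t).data) == pytest.approx(0.0)

    def test_disjoint_prediction_approaches_one(self):
        p = _mask((4, 4), [(0, 0)]).astype(np.float64)
        t = _mask((4, 4), [(3, 3)])
        assert float(dice_loss(p, t, eps=1e-12).data) == pytest.approx(1.0, abs=1e-9)

    def test_hand_worked_value(self):
        # pred covers 4 px at prob 1, truth has 2 of them: dice = 2*2/(4+2)
        p = _mask((4, 4), [(0, 0), (0, 1), (1, 0), (1, 1)]).astype(np.float64)
        t = _mask((4, 4), [(0, 0), (0, 1)])
        loss = float(dice_loss(p, t, eps=0.0).data)
        assert loss == pytest.approx(1 - 4 / 6)

    def test_both_empty_is_zero_loss(self):
        z = np.zeros((3, 3))
        assert float(dice_loss(z, z).data) == pytest.approx(0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice_loss(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_gradient_points_toward_truth(self, rng):
        """Backprop must push probabilities up on truth pixels, down elsewhere."""
        from dfaunet._autodiff.tensor import Parameter
        t = _mask((5, 5), [(2, 2), (2, 3)])
        p = Parameter(np.full((5, 5), 0.5))
        loss = dice_loss(p, t)
        loss.backward()
        assert (p.grad[t == 1] < 0).all()
        assert (p.grad[t == 0] > 0).all()


# ---------------------------------------------------------------------------
# confusion counts and overlap metrics
# ---------------------------------------------------------------------------

class TestConfusion:
    def test_full_enumeration_on_toy_grid(self):
        pred = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0]], np.uint8)
        truth = np.array([[1, 0, 0], [0, 1, 1], [0, 0, 0]], np.uint8)
        cs = confusion_counts(pred, truth)
        assert (cs.tp, cs.fp, cs.fn, cs.tn) == (2, 1, 1, 5)
        assert cs.total == 9

    def test_identical_and_complementary(self):
        m = _mask((3, 3), [(0, 0), (2, 2)])
        cs = confusion_counts(m, m)
        assert cs.fp == cs.fn == 0 and cs.tp == 2
        cs2 = confusion_counts(m, 1 - m)
        assert cs2.tp == cs2.tn == 0

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion_counts(np.array([[0, 2]]), np.array([[0, 1]]))

    def test_overlap_metrics_hand_worked(self):
        om = overlap_metrics(ConfusionSets(tp=2, fp=1, tn=5, fn=1))
        assert om["dice"] == pytest.approx(2 / 3)
        assert om["iou"] == pytest.approx(1 / 2)
        assert om["precision"] == pytest.approx(2 / 3)
        assert om["specificity"] == pytest.approx(5 / 6)
        assert om["degenerate"] is False

    def test_dice_iou_identity(self, rng):
        """Dice = 2*IoU/(1+IoU) must hold for any confusion counts."""
        for _ in range(20):
            tp, fp, fn = rng.integers(1, 50, size=3)
            om = overlap_metrics(ConfusionSets(int(tp), int(fp), 10, int(fn)))
            assert om["dice"] == pytest.approx(2 * om["iou"] / (1 + om["iou"]))

    def test_empty_convention(self):
        om = overlap_metrics(ConfusionSets(tp=0, fp=0, tn=9, fn=0))
        assert om["dice"] == 1.0 and om["iou"] == 1.0
        assert om["degenerate"] is True


# ---------------------------------------------------------------------------
# HD95
# ---------------------------------------------------------------------------

class TestHD95:
    def test_identical_masks_give_zero(self):
        m = _mask((8, 8), [(2, 2), (2, 3), (3, 2), (3, 3)])
        assert hd95(m, m) == pytest.approx(0.0)

    def test_two_pixel_euclidean_distance(self):
        a = _mask((8, 8), [(0, 0)])
        b = _mask((8, 8), [(3, 4)])
        assert hd95(a, b) == pytest.approx(5.0)  # 3-4-5 triangle

    def test_shifted_square_oracle(self):
        """A solid square shifted by (0, 2): every boundary point of one set
        is at most 2 from the other, and the extreme column is exactly 2."""
        a = np.zeros((10, 10), np.uint8)
        a[2:6, 2:6] = 1
        b = np.roll(a, 2, axis=1)
        d = hd95(a, b, q=100.0)  # exact Hausdorff for a clean hand check
        assert d == pytest.approx(2.0)

    def test_symmetry(self, rng):
        a = (rng.random((12, 12)) > 0.6).astype(np.uint8)
        b = (rng.random((12, 12)) > 0.6).astype(np.uint8)
        assert hd95(a, b) == pytest.approx(hd95(b, a))

    def test_translation_invariance(self):
        a = _mask((16, 16), [(4, 4), (4, 5), (5, 4)])
        b = _mask((16, 16), [(8, 9), (9, 8)])
        assert hd95(np.roll(a, 3, 0), np.roll(b, 3, 0)) == pytest.approx(hd95(a, b))

    def test_at_most_exact_hausdorff(self, rng):
        a = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        b = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        assert hd95(a, b) <= hd95(a, b, q=100.0) + 1e-12

    def test_backends_agree(self, rng):
        for _ in range(50):
            a = (rng.random((9, 9)) > 0.55).astype(np.uint8)
            b = (rng.random((9, 9)) > 0.55).astype(np.uint8)
            if not a.any() or not b.any():
                continue
            for pts in ("boundary", "foreground"):
                assert hd95(a, b, points=pts, backend="kdtree") == pytest.approx(
                    hd95(a, b, points=pts, backend="bruteforce"))

    def test_empty_mask_is_undefined(self):
        z = np.zeros((5, 5), np.uint8)
        m = _mask((5, 5), [(2, 2)])
        assert hd95(z, m) is None
        assert hd95(m, z) is None
        assert hd95(z, z) is None

    def test_bad_arguments(self):
        m = _mask((5, 5), [(2, 2)])
        with pytest.raises(ValueError, match="backend"):
            hd95(m, m, backend="gpu")
        with pytest.raises(ValueError, match="points"):
            hd95(m, m, points="volume")

    def test_boundary_of_solid_square(self):
        m = np.zeros((8, 8), np.uint8)
        m[2:6, 2:6] = 1
        pts = {tuple(p) for p in boundary_points(m)}
        interior = {(3, 3), (3, 4), (4, 3), (4, 4)}
        assert pts.isdisjoint(interior)
        assert len(pts) == 12  # 4x4 square has 12 edge pixels


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

class TestReport:
    def test_aggregate_and_serialisation(self, tmp_path):
        truth = _mask((6, 6), [(2, 2), (2, 3)])
        report = MetricsReport.from_masks([(truth, truth),
                                           (np.zeros_like(truth), truth)],
                                          image_ids=["a", "b"])
        agg = report.aggregate()
        assert agg["n_images"] == 2
        assert agg["dice_mean"] == pytest.approx(0.5)
        assert agg["hd95_undefined_count"] == 1
        payload = json.loads(report.to_json(tmp_path / "r.json"))
        assert [r["image_id"] for r in payload["rows"]] == ["a", "b"]
        report.to_csv(tmp_path / "r.csv")
        header = (tmp_path / "r.csv").read_text().splitlines()[0]
        assert header.startswith("image_id,dice")

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MetricsReport().aggregate()
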