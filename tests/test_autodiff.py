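"""Gradient and contract checks for the autodiff engine.

Every differentiable operation is verified against central finite
differences in float64; module plumbing (parameter discovery, state dict
round trips, optimiser/scheduler contracts) is checked separately.
"""

import numpy as np
import pytest

from dfaunet._autodiff import Tensor, as_tensor, concat
from dfaunet._autodiff import functional as F
from dfaunet._autodiff import nn
from dfaunet._autodiff.optim import Adam, StepLR
from dfaunet._autodiff.tensor import Parameter

from conftest import gradcheck


def _p(rng, *shape, scale=1.0):
    return Parameter(rng.standard_normal(shape) * scale)


# ---------------------------------------------------------------------------
# convolution family
# ---------------------------------------------------------------------------

class TestConvGradients:
    def test_conv2d_dense(self, rng):
        x, w, b = _p(rng, 2, 3, 6, 6), _p(rng, 4, 3, 3, 3, scale=0.3), _p(rng, 4, scale=0.1)
        gradcheck(lambda: F.conv2d(x, w, b, stride=1, padding=1), [x, w, b])

    def test_conv2d_strided(self, rng):
        x, w, b = _p(rng, 2, 3, 9, 9), _p(rng, 4, 3, 3, 3, scale=0.3), _p(rng, 4, scale=0.1)
        gradcheck(lambda: F.conv2d(x, w, b, stride=2, padding=1), [x, w, b])

    def test_conv2d_pointwise(self, rng):
        x, w, b = _p(rng, 2, 5, 4, 4), _p(rng, 3, 5, 1, 1, scale=0.3), _p(rng, 3, scale=0.1)
        gradcheck(lambda: F.conv2d(x, w, b), [x, w, b])

    def test_conv2d_depthwise_7x7(self, rng):
        x, w = _p(rng, 2, 4, 8, 8), _p(rng, 4, 1, 7, 7, scale=0.2)
        gradcheck(lambda: F.conv2d(x, w, None, padding=3, groups=4), [x, w])

    def test_conv2d_grouped(self, rng):
        x, w = _p(rng, 2, 4, 6, 6), _p(rng, 6, 2, 3, 3, scale=0.3)
        gradcheck(lambda: F.conv2d(x, w, None, padding=1, groups=2), [x, w])

    def test_conv_transpose(self, rng):
        x, w, b = _p(rng, 2, 3, 4, 4), _p(rng, 3, 2, 2, 2, scale=0.3), _p(rng, 2, scale=0.1)
        gradcheck(lambda: F.conv_transpose2d(x, w, b, stride=2), [x, w, b])

    def test_conv2d_group_mismatch_raises(self, rng):
        x, w = _p(rng, 1, 4, 5, 5), _p(rng, 4, 1, 3, 3)
        with pytest.raises(ValueError):
            F.conv2d(x, w, None, groups=3)


# ---------------------------------------------------------------------------
# resampling / pooling / normalisation / non-linearities
# ---------------------------------------------------------------------------

class TestOpGradients:
    def test_max_pool(self, rng):
        x = _p(rng, 2, 3, 6, 6)
        gradcheck(lambda: F.max_pool2d(x, 2), [x])

    @pytest.mark.parametrize("size", [(8, 8), (3, 3)])
    def test_bilinear_resize(self, rng, size):
        x = _p(rng, 2, 2, 5, 5)
        gradcheck(lambda: F.bilinear_resize(x, size), [x])

    def test_softmax(self, rng):
        x = _p(rng, 3, 5)
        coef = rng.standard_normal((3, 5))  # plain sum is constant per row
        gradcheck(lambda: F.softmax(x, axis=-1) * coef, [x])

    @pytest.mark.parametrize("op", [F.sigmoid, F.relu, F.gelu,
                                    lambda t: F.leaky_relu(t, 0.01)])
    def test_elementwise(self, rng, op):
        x = _p(rng, 3, 4, 2, 2)
        x.data += 0.05  # keep away from the ReLU kink where FD is invalid
        gradcheck(lambda: op(x), [x])

    def test_layer_norm_channels(self, rng):
        x, w, b = _p(rng, 2, 5, 3, 3), _p(rng, 5), _p(rng, 5)
        gradcheck(lambda: F.layer_norm_channels(x, w, b), [x, w, b])

    def test_batch_norm_train(self, rng):
        x, w, b = _p(rng, 3, 4, 4, 4), _p(rng, 4), _p(rng, 4)
        coef = rng.standard_normal((3, 4, 4, 4))  # break scale invariance
        rm, rv = np.zeros(4), np.ones(4)

        def fn():
            return F.batch_norm(x, w, b, rm.copy(), rv.copy(), training=True) * coef

        gradcheck(fn, [x, w, b])

    def test_batch_norm_eval(self, rng):
        x, w, b = _p(rng, 2, 4, 3, 3), _p(rng, 4), _p(rng, 4)
        rm = rng.standard_normal(4)
        rv = rng.random(4) + 0.5
        gradcheck(lambda: F.batch_norm(x, w, b, rm, rv, training=False), [x, w, b])

    def test_batch_norm_updates_running_stats(self, rng):
        x = as_tensor(rng.standard_normal((4, 2, 5, 5)))
        w, b = Parameter(np.ones(2)), Parameter(np.zeros(2))
        rm, rv = np.zeros(2), np.ones(2)
        F.batch_norm(x, w, b, rm, rv, training=True, momentum=0.1)
        expected_mean = 0.1 * x.data.mean(axis=(0, 2, 3))
        np.testing.assert_allclose(rm, expected_mean, rtol=1e-10)
        assert not np.allclose(rv, 1.0)

    def test_tensor_core_ops(self, rng):
        a, b = _p(rng, 3, 4), _p(rng, 4, 2)
        gradcheck(lambda: a @ b, [a, b])
        c, d = _p(rng, 2, 3), _p(rng, 2, 3)
        gradcheck(lambda: concat([c, d], axis=0), [c, d])
        e = _p(rng, 4, 4)
        gradcheck(lambda: e[1:3, :2], [e])
        gradcheck(lambda: (e.mean() + e / 3.0), [e])


# ---------------------------------------------------------------------------
# softmax semantics and determinism
# ---------------------------------------------------------------------------

def test_softmax_rows_are_stochastic(rng):
    x = as_tensor(rng.standard_normal((5, 7)) * 10)
    s = F.softmax(x, axis=-1).data
    np.testing.assert_allclose(s.sum(axis=-1), 1.0, atol=1e-6)
    assert (s >= 0).all()


def test_bilinear_resize_identity(rng):
    x = as_tensor(rng.random((1, 2, 6, 6)))
    np.testing.assert_allclose(F.bilinear_resize(x, (6, 6)).data, x.data, atol=1e-7)


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------

class TestModuleSystem:
    def test_nested_list_parameters_are_found(self):
        class Outer(nn.Module):
            def __init__(self):
                super().__init__()
                self.stages = [[nn.Conv2d(2, 2, 1), nn.Conv2d(2, 2, 1)],
                               [nn.Conv2d(2, 3, 3)]]

        names = dict(Outer().named_parameters())
        assert len(names) == 6  # three convs x (weight, bias)
        assert "stages.0.1.weight" in names

    def test_state_dict_roundtrip(self):
        m1 = nn.Sequential(nn.Conv2d(3, 4, 3, rng=np.random.default_rng(1)),
                           nn.BatchNorm2d(4))
        m2 = nn.Sequential(nn.Conv2d(3, 4, 3, rng=np.random.default_rng(2)),
                           nn.BatchNorm2d(4))
        m2.load_state_dict(m1.state_dict())
        for (n1, p1), (n2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_state_dict_shape_mismatch_names_tensor(self):
        m = nn.Conv2d(3, 4, 3)
        bad = {k: (v if k != "weight" else np.zeros((1, 1, 1, 1)))
               for k, v in m.state_dict().items()}
        with pytest.raises(ValueError, match="weight"):
            m.load_state_dict(bad)

    def test_strict_load_reports_missing(self):
        m = nn.Conv2d(3, 4, 3)
        with pytest.raises(KeyError, match="missing"):
            m.load_state_dict({})


# ---------------------------------------------------------------------------
# optimiser and scheduler
# ---------------------------------------------------------------------------

class TestOptim:
    def test_adam_reduces_quadratic(self):
        p = Parameter(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            loss = (p * p).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2

    def test_decoupled_weight_decay_shrinks_weights(self):
        p = Parameter(np.array([1.0]))
        opt = Adam([p], lr=0.1, weight_decay=0.5)
        p.grad = np.array([0.0])
        m_before = float(p.data[0])
        opt.step()
        # decay multiplies by (1 - lr*wd); the gradient term is zero
        assert float(p.data[0]) == pytest.approx(m_before * (1 - 0.1 * 0.5))

    def test_steplr_schedule_contract(self):
        opt = Adam([Parameter(np.zeros(1))], lr=1e-4)
        sched = StepLR(opt, step_size=90, gamma=0.1)
        sched.set_epoch(89)
        assert opt.lr == pytest.approx(1e-4)
        sched.set_epoch(90)
        assert opt.lr == pytest.approx(1e-5)
        sched.set_epoch(180)
        assert opt.lr == pytest.approx(1e-6)


def test_backward_accumulates_over_reuse(rng):
    x = _p(rng, 3)
    y = (x * x + x * 2.0).sum()
    y.backward()
    np.testing.assert_allclose(x.grad, 2 * x.data + 2.0, rtol=1e-10)
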