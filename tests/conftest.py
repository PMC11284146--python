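"""Shared fixtures: tiny model configurations and deterministic RNGs."""

import numpy as np
import pytest

from dfaunet.data import SynthConfig, generate_synthetic_dataset
from dfaunet.model import DFAUNet, ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    """Width-16 model for shape/plumbing tests (fast to build and run)."""
    return DFAUNet(ModelConfig(base_width=16, decoder_hidden=32, seed=0))


@pytest.fixture(scope="session")
def tiny_samples():
    """Eight 64x64 synthetic samples shared by data-dependent tests."""
    return generate_synthetic_dataset(SynthConfig(n_images=8, image_size=64, seed=2))


def gradcheck(fn, params, eps=1e-5, tol=1e-5):
    """Central-difference gradient check; returns the worst relative error."""
    out = fn()
    out.sum().backward()
    worst = 0.0
    for p in params:
        analytic = p.grad.copy()
        numeric = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = p.data[i]
            p.data[i] = old + eps
            lp = float(fn().sum().data)
            p.data[i] = old - eps
            lm = float(fn().sum().data)
            p.data[i] = old
            numeric[i] = (lp - lm) / (2 * eps)
        scale = max(float(np.abs(numeric).max()), 1e-8)
        worst = max(worst, float(np.abs(analytic - numeric).max()) / scale)
        p.grad = None
    assert worst < tol, f"gradient mismatch: relative error {worst:.3e}"
    return worst
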