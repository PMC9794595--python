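from dataclasses import replace

import numpy as np
import pytest

from rdaunet import network, nn, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config():
    """Smallest config that still exercises every block."""
    return network.ModelConfig(variant="rdau", base_channels=4, depth=2, K=2)


@pytest.fixture
def seeded():
    nn.set_global_seed(1234)


@pytest.fixture(scope="session")
def overfit_scenes():
    """Eight 128x128 scenes with a few ghosts/bubbles: separable enough to
    overfit, cluttered enough to be non-trivial."""
    spec = synthetic.SceneSpec(width=128, height=128, n_organoids=10,
                               radius_mean=9.0, n_ghosts=3, n_bubbles=2, seed=0)
    out = []
    for i in range(8):
        img, truth = synthetic.make_scene(replace(spec, seed=100 + i))
        out.append((img, truth.mask))
    return out


@pytest.fixture(scope="session")
def hard_scenes():
    """Ten harder 64x64 scenes (heavy clutter, noise, blur) where precision
    and recall stay away from 1, so loss-weighting effects are visible."""
    spec = synthetic.SceneSpec(width=64, height=64, n_organoids=5,
                               radius_mean=7.0, n_ghosts=7, n_bubbles=3,
                               noise_sd=0.06, blur_sigma=1.5,
                               illumination_gradient=0.25, seed=0)
    out = []
    for i in range(10):
        img, truth = synthetic.make_scene(replace(spec, seed=200 + i))
        out.append((img, truth.mask))
    return out
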