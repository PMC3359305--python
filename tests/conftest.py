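"""Shared fixtures: small synthetic inputs generated at test time."""

import numpy as np
import pytest
from hypothesis import settings

from backmatch import make_fractal_texture, preprocess_gray, render_scene
from backmatch.synthetic import reference_scene_spec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def beta2_texture():
    """One 256x256 fractal texture with exponent 2 (raw, unprocessed)."""
    return make_fractal_texture(256, 256, 2.0, seed=7)


@pytest.fixture(scope="session")
def reference_scene():
    """Reference world, seed 0: (raw scene, truth, preprocessed GrayScene)."""
    scene, truth = render_scene(reference_scene_spec(0))
    return scene, truth, preprocess_gray(scene)
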