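import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles as `oracles`

from octaquant import ScanGeometry, SceneParams, compute_all, generate_scene


@pytest.fixture(scope="session")
def macula():
    return ScanGeometry.macula_3mm()


@pytest.fixture(scope="session")
def small_geometry():
    return ScanGeometry(1.0, 1.0, 32, 32)


@pytest.fixture(scope="session")
def clean_scene():
    """Default noise-free scene: circular FAZ, ring, trees, capillary mesh."""
    params = SceneParams(noise_sigma=0.0, speckle_strength=0.0, rng_seed=1)
    image, truth = generate_scene(params)
    return params, image, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Default scene with the standard noise model."""
    params = SceneParams(rng_seed=7)
    image, truth = generate_scene(params)
    return params, image, truth


@pytest.fixture(scope="session")
def noisy_result(noisy_scene):
    params, image, truth = noisy_scene
    return compute_all(image, image_id="noisy", return_intermediates=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
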