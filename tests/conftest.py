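import numpy as np
import pytest

from comonod.synth import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20170)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 512 px scene shared by pipeline-level tests."""
    spec = SceneSpec(seed=3, width_px=512, height_px=512, n_objects=9)
    img, gt = generate_scene(spec)
    return spec, img, gt
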