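import numpy as np
import pytest

from rownav import synthfield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dark_scene():
    """A night scene with strong axial illumination falloff (mean luminance low)."""
    cfg = synthfield.SceneConfig(seed=7, illum_min=0.12, weed_count=4)
    return synthfield.generate_scene(cfg)


@pytest.fixture
def clean_scene():
    """Noise-free geometry: no jitter, no gaps, flat light."""
    return synthfield.generate_scene(synthfield.SceneConfig(seed=3))
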