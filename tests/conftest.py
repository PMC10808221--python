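import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from stedclust import AnalysisParams, PixelImage, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240124)


@pytest.fixture
def default_params():
    return AnalysisParams()


def make_image(values, pixel_size_nm=20.0, channel=None) -> PixelImage:
    return PixelImage(np.asarray(values, dtype=np.float64), pixel_size_nm, channel)


def small_sim_config(**overrides) -> SimConfig:
    """A fast simulator config for tests; overrides win."""
    base = dict(image_size_px=(256, 256), seed=7)
    base.update(overrides)
    return SimConfig(**base)
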