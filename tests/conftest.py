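import numpy as np
import pytest

from jetvision import PipelineConfig, default_nozzle_template
from jetvision.synthetic_jet import SceneParams


@pytest.fixture
def cfg() -> PipelineConfig:
    """Reference defaults at a 1 um/px scale."""
    return PipelineConfig(pixel_size_um=1.0)


@pytest.fixture
def template():
    return default_nozzle_template()


@pytest.fixture
def scene() -> SceneParams:
    """Noiseless default scene (miss)."""
    return SceneParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
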