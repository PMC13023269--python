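import numpy as np
import pytest

from wattdet import ModelConfig, build_model
from wattdet.synthetic import items_from_specs, random_specs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_full_model():
    """Full-module detector for 64 px inputs (shared, read-only)."""
    cfg = ModelConfig(use_scsa=True, use_wfu=True, use_wtconv=True,
                      input_size=64)
    return build_model(cfg, seed=3)


@pytest.fixture(scope="session")
def tiny_baseline_model():
    return build_model(ModelConfig(input_size=64), seed=3)


@pytest.fixture(scope="session")
def synth_items():
    """Eight deterministic 64 px synthetic scenes."""
    return items_from_specs(random_specs(8, seed=11, image_size=64))
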