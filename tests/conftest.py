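import numpy as np
import pytest

from echophase import ModelConfig, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def synth_cfg():
    return SyntheticConfig(seed=7)


@pytest.fixture
def tiny_model_cfg():
    """Smallest config that survives three conv/pool stages (22 -> 1)."""
    return ModelConfig(input_shape=(22, 22, 1), conv_filters=(2, 3, 4),
                       dense_width=5, n_classes=2)


@pytest.fixture
def tiny_model_cfg3():
    return ModelConfig(input_shape=(22, 22, 1), conv_filters=(2, 3, 4),
                       dense_width=5, n_classes=3)
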