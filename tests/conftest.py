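import numpy as np
import pytest

from fedgh.pose import PoseNet, PoseNetConfig


@pytest.fixture(scope="session")
def micro_config() -> PoseNetConfig:
    """Very small network for fast structural tests: 32×32 in, 8×8 maps."""
    return PoseNetConfig(
        input_size=32, heatmap_size=8,
        backbone_channels=(4, 8), deconv_specs=((8, 3, 1),),
        sigma=1.5,
    )


@pytest.fixture()
def micro_model(micro_config) -> PoseNet:
    return PoseNet(micro_config, seed=0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
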