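import numpy as np
import pytest

from tmdunet.architecture import NetworkConfig, build_model
from tmdunet.synthetic import SynthSpec, generate_blobs


@pytest.fixture(scope="session")
def tiny_config():
    """A narrow TMD-Unet at the smallest legal input size."""
    return NetworkConfig(variant="tmdunet", input_height=32, input_width=32,
                         base_filters=2)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=0)


@pytest.fixture(scope="session")
def blob_data():
    spec = SynthSpec(n_images=4, size=32, seed=11,
                     foreground_fraction=(0.05, 0.5))
    return generate_blobs(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
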