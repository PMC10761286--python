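import numpy as np
import pytest

from bubblesim import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def baseline_config():
    """The study's baseline geometry: 680 nodes, 10 bubbles, 400 links."""
    return NetworkConfig.from_modularity(680, 10, 400.0, 5.0)
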