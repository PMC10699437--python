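import numpy as np
import pytest

from hra.fixtures import four_zone_partition, published_weight_tree
from hra.synth import SyntheticConfig, generate_panel


@pytest.fixture(scope="session")
def tree():
    return published_weight_tree()


@pytest.fixture(scope="session")
def partition31():
    return four_zone_partition()


@pytest.fixture(scope="session")
def synth_bundle():
    """Default-shaped synthetic world: 31 units, 4 zones, 9 indicators, 12 years."""
    cfg = SyntheticConfig(seed=7)
    return generate_panel(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
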