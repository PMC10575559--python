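import numpy as np
import pytest

from tommarket import TaskConfig, build_grid, build_hierarchy


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def default_hierarchy(default_config):
    return build_hierarchy(default_config)


@pytest.fixture(scope="session")
def default_grid(default_config):
    return build_grid(default_config)


@pytest.fixture(scope="session")
def coarse_config():
    """Three-point lattice {0, 5, 10} for hand-checkable computations."""
    return TaskConfig(grid_step=5.0)


@pytest.fixture(scope="session")
def coarse_hierarchy(coarse_config):
    return build_hierarchy(coarse_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230820)
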