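import numpy as np
import pytest

from metapred import SimulationParams, SyntheticConfig, build_fractal_layout


@pytest.fixture(scope="session")
def layout81():
    """The full 81-patch fractal array (4 levels, default spacings)."""
    return build_fractal_layout(4)


@pytest.fixture(scope="session")
def layout9():
    """A small 9-patch array for cheap simulation tests."""
    return build_fractal_layout(2)


@pytest.fixture()
def params():
    return SimulationParams()


@pytest.fixture()
def synth_cfg():
    return SyntheticConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20140517)
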