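import numpy as np
import pytest

from octvolsr import NetworkConfig, ScanGrid, default_spec, make_triplet, render
from octvolsr.volumes import Volume


@pytest.fixture(scope="session")
def desk_triplet():
    """One speckled 64 x 64 x 32 phantom triplet (the desk-scale grid)."""
    return make_triplet(render(default_spec(seed=11)))


@pytest.fixture(scope="session")
def tiny_triplet():
    """A 32 x 16 x 16 phantom triplet for the cheapest model tests."""
    spec = default_spec(ScanGrid(nx=32, ny=16, nz=16), seed=5)
    return make_triplet(render(spec))


@pytest.fixture
def desk_config():
    return NetworkConfig(depth=3, base_channels=4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    return Volume(rng.random((12, 16, 8), dtype=np.float32))
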