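import numpy as np
import pytest

from pharmgbc import make_atlas


@pytest.fixture(scope="session")
def atlas_small():
    """40 parcels, 4 networks — fast unit-test geometry."""
    return make_atlas(40, 4, seed=1)


@pytest.fixture(scope="session")
def atlas_200():
    """200 parcels, 12 networks — the desk-scale study geometry."""
    return make_atlas(200, 12, seed=0)


@pytest.fixture(scope="session")
def dist_200(atlas_200):
    return atlas_200.distances()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
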