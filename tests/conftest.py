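import numpy as np
import pytest

from neuroturb.geometry import generate_parcellation, pairwise_distances


@pytest.fixture(scope="session")
def geom30():
    return generate_parcellation(30, seed=1)


@pytest.fixture(scope="session")
def dist30(geom30):
    return pairwise_distances(geom30)


@pytest.fixture(scope="session")
def geom100():
    return generate_parcellation(100, seed=1)


@pytest.fixture(scope="session")
def dist100(geom100):
    return pairwise_distances(geom100)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
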