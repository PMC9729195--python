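import numpy as np
import pytest

from nexis.datatypes import Connectome, GeneVector
from nexis.synthetic import SyntheticSpec, make_dataset


@pytest.fixture
def two_node():
    return Connectome(np.array([[0.0, 1.0], [1.0, 0.0]]), ("a", "b"))


@pytest.fixture
def three_node():
    # asymmetric on purpose; symmetrization is part of what tests exercise
    return Connectome(np.array([[0.0, 2.0, 0.0],
                                [1.0, 0.0, 3.0],
                                [0.0, 0.0, 0.0]]), ("r1", "r2", "r3"))


@pytest.fixture(scope="session")
def desk_dataset():
    """Default desk-scale synthetic study (40 regions, 10% noise)."""
    return make_dataset(SyntheticSpec(rng_seed=0))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noiseless, fully quantified study for exact self-consistency checks."""
    return make_dataset(SyntheticSpec(rng_seed=5, noise_sd=0.0, quantified_frac=1.0,
                                      n_regions_per_hemi=10))


def random_system(seed: int, n_per_hemi: int = 10):
    """A random connectome + normalized gene vector pair for property tests."""
    ds = make_dataset(SyntheticSpec(rng_seed=seed, n_regions_per_hemi=n_per_hemi))
    return ds.connectome, ds.gene


@pytest.fixture
def gene_uniform():
    def _make(conn, value=0.5):
        return GeneVector(np.full(conn.n, value), name="const", normalized=True)
    return _make
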