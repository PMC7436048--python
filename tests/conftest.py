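import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from enosefs.fitness import make_split
from enosefs.synthetic_data import make_reference_benchmark, make_tabular_dataset


@pytest.fixture(scope="session")
def reference_split():
    """The canonical 128-feature benchmark split (seed 0)."""
    return make_reference_benchmark(seed=0)


@pytest.fixture(scope="session")
def tabular_split():
    """Small 10-feature instance for exact-enumeration studies."""
    table = make_tabular_dataset(n_samples=60, n_features=10, n_informative=3,
                                 n_classes=3, seed=7)
    return make_split(table, split_fraction=0.7, seed=7)


@pytest.fixture(scope="session")
def separable_split():
    """Two well-separated Gaussian classes; any sensible mask classifies perfectly."""
    rng = np.random.default_rng(11)
    n_per, dim = 30, 6
    a = rng.normal(-5.0, 0.1, (n_per, dim))
    b = rng.normal(5.0, 0.1, (n_per, dim))
    from enosefs.containers import FeatureTable

    table = FeatureTable(np.vstack([a, b]), np.r_[np.zeros(n_per, int), np.ones(n_per, int)])
    return make_split(table, split_fraction=0.7, seed=3)
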