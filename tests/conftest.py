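import numpy as np
import pytest
from hypothesis import settings

from rflkit.dataio import FeatureTable
from rflkit.simdata import generate_dataset, reference_sim_spec

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def separable_table() -> FeatureTable:
    """Well-separated 8-class synthetic table (reference conditions)."""
    return generate_dataset(reference_sim_spec(seed=7), n_rows=2000, seed=7)


@pytest.fixture(scope="session")
def two_class_blobs():
    """Linearly separable 2-class 9-feature point cloud."""
    rng = np.random.default_rng(0)
    n = 600
    X = np.vstack([rng.normal(0.0, 1.0, (n // 2, 9)),
                   rng.normal(3.0, 1.0, (n // 2, 9))])
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    perm = rng.permutation(n)
    return X[perm], y[perm]
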