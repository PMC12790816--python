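import numpy as np
import pandas as pd
import pytest

from jointmds.dissimilarity import (
    geodesic_distances,
    normalize_dissimilarity,
    pairwise_euclidean,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_feature_matrix(rng):
    """5 samples x 3 features with string IDs."""
    return pd.DataFrame(
        rng.standard_normal((5, 3)),
        index=[f"s{i}" for i in range(5)],
        columns=["f1", "f2", "f3"],
    )


@pytest.fixture(scope="session")
def gaussian_cloud():
    """A 50-point 5-D Gaussian sample, the stock self-alignment instance."""
    return np.random.default_rng(0).standard_normal((50, 5))


@pytest.fixture(scope="session")
def gaussian_geodesic(gaussian_cloud):
    """Normalized geodesic (k=5) dissimilarities of the Gaussian cloud."""
    E = pairwise_euclidean(gaussian_cloud)
    return normalize_dissimilarity(geodesic_distances(E, 5))


def random_dissimilarity(rng, n):
    """A valid random dissimilarity matrix (not necessarily metric)."""
    M = rng.uniform(0.1, 1.0, size=(n, n))
    D = (M + M.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D
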