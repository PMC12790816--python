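"""Pairwise dissimilarity matrices: Euclidean and geodesic (k-NN graph) distances.

Geodesic distances approximate distance along the data manifold: build a
k-nearest-neighbour graph weighted by Euclidean distance, then take all-pairs
shortest paths.  Disconnected graphs are repaired by bridging components at
their closest point pair so that no sample is ever dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

_TINY_EDGE = 1e-300  # stand-in weight for zero-length edges in sparse graphs

__all__ = [
    "pairwise_euclidean",
    "knn_graph",
    "geodesic_distances",
    "normalize_dissimilarity",
    "check_dissimilarity",
]


def check_dissimilarity(D: np.ndarray, name: str = "D") -> np.ndarray:
    """Validate a square symmetric nonnegative zero-diagonal matrix."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"{name} must be square, got shape {D.shape}")
    if not np.isfinite(D).all():
        raise ValueError(f"{name} contains non-finite entries")
    if (D < 0).any():
        raise ValueError(f"{name} contains negative entries")
    if not np.allclose(D, D.T):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError(f"{name} has a nonzero diagonal")
    return D


def pairwise_euclidean(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """All-pairs L2 distances between the rows of a feature matrix."""
    values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    return squareform(pdist(values, metric="euclidean"))


def knn_graph(D: np.ndarray, k: int) -> csr_matrix:
    """Union-symmetrized k-nearest-neighbour graph of a dissimilarity matrix.

    Each node is linked to its k nearest others; an edge is kept if either
    endpoint selects it.  Equidistant neighbours are broken in favour of the
    smaller sample index.  Returns a symmetric sparse matrix of edge weights
    with no self-loops.
    """
    D = check_dissimilarity(D)
    n = D.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    # stable argsort on (distance, index); exclude self at distance 0
    order = np.argsort(D + np.diag(np.full(n, np.inf)), axis=1, kind="stable")
    neigh = order[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = neigh.ravel()
    # zero-length edges (coincident points) get a negligible positive weight:
    # sparse arithmetic drops stored zeros, which would disconnect duplicates
    data = np.maximum(D[rows, cols], _TINY_EDGE)
    A = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return A.maximum(A.T)  # union symmetrization; weights already symmetric


def _bridge_components(G: csr_matrix, D: np.ndarray) -> csr_matrix:
    """Connect graph components by the Euclidean distance of their closest pair."""
    G = G.tolil()
    while True:
        n_comp, labels = connected_components(G.tocsr(), directed=False)
        if n_comp == 1:
            return G.tocsr()
        logger.warning(
            "kNN graph has %d disconnected components; bridging closest pairs", n_comp
        )
        # bridge component 0 to its nearest other component, then re-check
        in0 = labels == 0
        sub = D[np.ix_(in0, ~in0)]
        i_loc, j_loc = np.unravel_index(np.argmin(sub), sub.shape)
        i = np.flatnonzero(in0)[i_loc]
        j = np.flatnonzero(~in0)[j_loc]
        G[i, j] = G[j, i] = max(D[i, j], _TINY_EDGE)


def geodesic_distances(D: np.ndarray, k: int) -> np.ndarray:
    """Shortest-path distances on the k-NN graph of ``D``.

    The result is symmetric with zero diagonal and entrywise >= ``D`` (a path
    through intermediate points can never undercut the direct Euclidean
    distance).  Disconnected components are bridged first, so every entry is
    finite.
    """
    G = knn_graph(D, k)
    G = _bridge_components(G, np.asarray(D, dtype=float))
    SP = shortest_path(G, method="D", directed=False)
    return (SP + SP.T) / 2.0  # exact symmetry against float drift


def normalize_dissimilarity(D: np.ndarray) -> np.ndarray:
    """Scale a dissimilarity matrix to [0, 1] by its maximum entry.

    Alignment mixes stress across modalities whose raw scales are not
    comparable; max-normalization puts them on one footing.
    """
    D = check_dissimilarity(D)
    m = D.max()
    if m <= 0:
        raise ValueError("cannot normalize an all-zero dissimilarity matrix")
    return D / m
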