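"""Labelled synthetic manifolds and their high-dimensional domain triplets.

Three classic manifolds — a bifurcating trajectory, a Swiss roll and a
circular frustum — are sampled with 300 points and 3 ground-truth groups,
then linearly projected into high-dimensional feature spaces (1000 and 2000
dimensions) with additive Gaussian noise.  A third, 500-dimensional domain is
derived from the pair: principal axes of the column-concatenated two domains
are applied to the first domain, plus N(0, 0.05²) noise.  The result is a
triplet of heterogeneous feature matrices with shared samples and labels,
the standard testbed for unsupervised three-domain alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ManifoldSample",
    "make_manifold",
    "project_domain",
    "make_third_domain",
    "make_triplet",
    "KINDS",
]

KINDS = ("bifurcation", "swiss_roll", "circular_frustum")


@dataclass
class ManifoldSample:
    """Low-dimensional coordinates plus 3-group labels for n samples."""

    coords: np.ndarray  # n × q, q in {2, 3}
    labels: np.ndarray  # n values in {1, 2, 3}

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def _bifurcation(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A 2-D trajectory that splits into two noisy branches at its midpoint.

    The branches leave at different angles and lengths: a mirror-symmetric
    fork would make branch identity unrecoverable from within-domain
    distances alone (any aligner could only guess which branch is which),
    which is not a property of real bifurcating-trajectory data.
    """
    t = rng.uniform(0.0, 2.0, size=n)
    x = t.copy()
    y = np.zeros(n)
    labels = np.ones(n, dtype=int)
    upper = (t > 1.0) & (rng.uniform(size=n) < 0.5)
    lower = (t > 1.0) & ~upper
    s_up = t[upper] - 1.0  # arc length along the branch
    x[upper] = 1.0 + s_up * np.cos(np.pi / 3.0)
    y[upper] = s_up * np.sin(np.pi / 3.0)
    s_lo = 0.7 * (t[lower] - 1.0)
    x[lower] = 1.0 + s_lo * np.cos(-np.pi / 7.0)
    y[lower] = s_lo * np.sin(-np.pi / 7.0)
    labels[upper] = 2
    labels[lower] = 3
    coords = np.column_stack([x, y]) + rng.normal(scale=0.05, size=(n, 2))
    return coords, labels


def _swiss_roll(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """The classic 3-D roll (t·cos t, h, t·sin t), labelled by three t-bands."""
    t = 1.5 * np.pi * (1.0 + 2.0 * rng.uniform(size=n))
    h = 21.0 * rng.uniform(size=n)
    coords = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    coords += rng.normal(scale=0.05, size=(n, 3))
    edges = np.quantile(t, [1 / 3, 2 / 3])
    labels = 1 + np.searchsorted(edges, t)
    return coords, labels.astype(int)


def _circular_frustum(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Points on a truncated-cone surface, labelled by three angular sectors."""
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    h = rng.uniform(0.0, 1.0, size=n)
    r = 1.0 + h  # radius widens from 1 to 2 along the height
    coords = np.column_stack([r * np.cos(theta), r * np.sin(theta), 2.0 * h])
    coords += rng.normal(scale=0.05, size=(n, 3))
    labels = 1 + (theta // (2.0 * np.pi / 3.0)).astype(int)
    return coords, np.clip(labels, 1, 3)


_GENERATORS = {
    "bifurcation": _bifurcation,
    "swiss_roll": _swiss_roll,
    "circular_frustum": _circular_frustum,
}


def make_manifold(kind: str, n: int = 300, seed: int = 0) -> ManifoldSample:
    """Sample a labelled manifold; deterministic per (kind, n, seed).

    Coordinates are standardized to zero mean and unit overall scale so the
    three manifolds feed the projection step on a common footing.
    """
    if kind not in _GENERATORS:
        raise ValueError(f"unknown manifold kind {kind!r}; choose from {KINDS}")
    if n < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    coords, labels = _GENERATORS[kind](n, rng)
    coords = coords - coords.mean(axis=0)
    coords = coords / coords.std()
    return ManifoldSample(coords=coords, labels=labels)


def _sample_ids(n: int) -> list[str]:
    return [f"s{i:04d}" for i in range(n)]


def project_domain(
    M: ManifoldSample, target_dim: int, noise_sd: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Linear random projection of manifold coordinates into ``target_dim`` space.

    The projection matrix has i.i.d. N(0, 1/q) entries (variance preserving);
    i.i.d. N(0, noise_sd²) noise is added to every output entry.
    """
    q = M.coords.shape[1]
    if target_dim < q:
        raise ValueError(f"target_dim must be >= intrinsic dimension {q}")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((q, target_dim)) / np.sqrt(q)
    X = M.coords @ A
    if noise_sd > 0:
        X = X + rng.normal(scale=noise_sd, size=X.shape)
    return pd.DataFrame(
        X,
        index=_sample_ids(M.n),
        columns=[f"f{j:04d}" for j in range(target_dim)],
    )


def make_third_domain(
    F1: pd.DataFrame,
    F2: pd.DataFrame,
    dim: int = 500,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Derive a third domain from a pair via principal axes of their union.

    The two matrices are column-concatenated (same samples), the top ``dim``
    right singular vectors of the centered combined matrix are taken as
    loadings, and the first domain is mapped through the domain-1 block of
    those loadings; i.i.d. N(0, noise_sd²) noise is added.  With n samples
    only min(n, p1+p2) principal axes exist; any remaining columns up to
    ``dim`` use a seeded orthonormal complement and therefore carry noise
    only.
    """
    if not F1.index.equals(F2.index):
        raise ValueError("the two domains must share sample IDs in the same order")
    p_total = F1.shape[1] + F2.shape[1]
    if dim > p_total:
        raise ValueError(f"dim={dim} exceeds the {p_total} combined features")
    combined = np.hstack([F1.to_numpy(float), F2.to_numpy(float)])
    centered = combined - combined.mean(axis=0)
    # right singular vectors = principal axes, ordered by explained variance
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    V = Vt.T  # p_total × r
    r = V.shape[1]
    if dim > r:
        rng = np.random.default_rng(seed)
        extra = rng.standard_normal((p_total, dim - r))
        extra -= V @ (V.T @ extra)  # orthogonalize against existing axes
        extra, _ = np.linalg.qr(extra)
        V = np.hstack([V, extra[:, : dim - r]])
    else:
        V = V[:, :dim]
    p1 = F1.shape[1]
    X1 = F1.to_numpy(float)
    X1c = X1 - X1.mean(axis=0)
    out = X1c @ V[:p1, :]
    if noise_sd > 0:
        rng_noise = np.random.default_rng(seed + 1)
        out = out + rng_noise.normal(scale=noise_sd, size=out.shape)
    return pd.DataFrame(
        out, index=F1.index, columns=[f"f{j:04d}" for j in range(dim)]
    )


def make_triplet(
    kind: str,
    seed: int = 0,
    n: int = 300,
    dims: tuple[int, int, int] = (1000, 2000, 500),
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """One manifold draw rendered as three heterogeneous feature domains.

    Returns (F1, F2, F3, labels): projections to ``dims[0]`` and ``dims[1]``
    dimensions plus the derived ``dims[2]``-dimensional third domain, all
    sharing sample IDs and labels.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
    M = make_manifold(kind, n=n, seed=seeds[0])
    F1 = project_domain(M, dims[0], noise_sd=noise_sd, seed=seeds[1])
    F2 = project_domain(M, dims[1], noise_sd=noise_sd, seed=seeds[2])
    F3 = make_third_domain(F1, F2, dim=dims[2], noise_sd=noise_sd, seed=seeds[3])
    labels = pd.Series(M.labels, index=F1.index, name="label")
    return F1, F2, F3, labels
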