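"""Weighted multidimensional scaling by SMACOF stress majorization.

The stress of a configuration Z against target dissimilarities D with
symmetric nonnegative weights W is the ordered-pair sum

    stress(Z, D, W) = sum_{i != j} W_ij (D_ij - ||z_i - z_j||)^2

(twice the i < j sum; the same convention is used everywhere in the package,
including the joint two-domain step).  Each SMACOF iteration applies the
Guttman transform, which never increases the stress.

The joint step used inside the two-domain alignment treats the coupling term
2λ Σ_ij P_ij ||z_i O − z'_j||² as extra stress toward target dissimilarity 0
with weight λP_ij per ordered cross pair, so a single Guttman update on the
stacked (n + n') configuration [Z·O ; Z'] with block dissimilarities
[[D, 0], [0, D']] and block weights [[W, λP], [λPᵀ, W']] majorizes the whole
joint objective.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

__all__ = [
    "init_embedding",
    "stress",
    "uniform_weights",
    "smacof_step",
    "weighted_mds",
    "joint_stress_step",
    "GuttmanSolver",
]


def init_embedding(n: int, d: int, seed: int) -> np.ndarray:
    """Random i.i.d. standard-normal n × d starting configuration."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    return np.random.default_rng(seed).standard_normal((n, d))


def uniform_weights(n: int) -> np.ndarray:
    """The default weight matrix: 1/n² on all off-diagonal pairs."""
    W = np.full((n, n), 1.0 / n**2)
    np.fill_diagonal(W, 0.0)
    return W


def _check_weights(W: np.ndarray, n: int) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.shape != (n, n):
        raise ValueError(f"weight matrix shape {W.shape} does not match n={n}")
    if (W < 0).any():
        raise ValueError("weights must be nonnegative")
    return W


def stress(Z: np.ndarray, D: np.ndarray, W: np.ndarray) -> float:
    """Weighted raw stress over ordered pairs i != j."""
    Z = np.asarray(Z, dtype=float)
    D = np.asarray(D, dtype=float)
    n = Z.shape[0]
    if D.shape != (n, n):
        raise ValueError(f"dissimilarity shape {D.shape} does not match n={n}")
    W = _check_weights(W, n)
    dist = cdist(Z, Z)
    diff = D - dist
    np.fill_diagonal(diff, 0.0)
    return float(np.sum(W * diff**2))


class GuttmanSolver:
    """Precomputed solver for the V-system of the Guttman transform.

    The update is Z⁺ = V⁺ B(Z) Z with V = diag(W·1) − W.  V is singular (the
    all-ones vector spans its null space) but B(Z)Z has zero column sums, so
    solving with the rank-completed positive-definite matrix V + c·11ᵀ gives
    the pseudo-inverse action exactly.  Factorized once per weight matrix.
    """

    def __init__(self, W: np.ndarray):
        n = W.shape[0]
        V = np.diag(W.sum(axis=1)) - W
        c = max(W.sum() / n**2, 1e-12)
        self._pinv: np.ndarray | None = None
        try:
            self._factor = cho_factor(V + c * np.ones((n, n)), lower=True)
        except np.linalg.LinAlgError:
            # weight graph not connected: rank-one completion is not enough
            self._pinv = np.linalg.pinv(V)
        self.n = n

    def solve(self, Y: np.ndarray) -> np.ndarray:
        if self._pinv is not None:
            return self._pinv @ Y
        return cho_solve(self._factor, Y)


def smacof_step(
    Z: np.ndarray,
    D: np.ndarray,
    W: np.ndarray,
    solver: GuttmanSolver | None = None,
) -> np.ndarray:
    """One Guttman-transform update; stress(result) <= stress(Z).

    Coincident points contribute nothing to the B matrix (the zero-distance
    term is skipped), the standard guard against division by zero.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    W = _check_weights(W, n)
    dist = cdist(Z, Z)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, D / np.where(dist > 0, dist, 1.0), 0.0)
    B = -W * ratio
    np.fill_diagonal(B, 0.0)
    np.fill_diagonal(B, -B.sum(axis=1))
    if solver is None:
        solver = GuttmanSolver(W)
    return solver.solve(B @ Z)


class MDSResult(NamedTuple):
    embedding: np.ndarray
    stress_trace: list[float]


def weighted_mds(
    D: np.ndarray,
    W: np.ndarray | None,
    d: int,
    init: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> MDSResult:
    """SMACOF from a given start until relative stress change < tol.

    Returns the final configuration and the per-iteration stress trace
    (starting with the stress of ``init``); the trace is non-increasing.
    With ``max_iter=0`` the initial configuration is returned unchanged.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if W is None:
        W = uniform_weights(n)
    Z = np.asarray(init, dtype=float)
    if Z.shape != (n, d):
        raise ValueError(f"init shape {Z.shape} does not match ({n}, {d})")
    solver = GuttmanSolver(np.asarray(W, dtype=float))
    trace = [stress(Z, D, W)]
    for _ in range(max_iter):
        Z = smacof_step(Z, D, W, solver=solver)
        trace.append(stress(Z, D, W))
        prev, cur = trace[-2], trace[-1]
        if prev - cur <= tol * max(prev, 1e-30):
            break
    return MDSResult(Z, trace)


def joint_stress_step(
    Z: np.ndarray,
    Z_prime: np.ndarray,
    D: np.ndarray,
    D_prime: np.ndarray,
    W: np.ndarray,
    W_prime: np.ndarray,
    P: np.ndarray,
    O: np.ndarray,
    lam: float,
    solver: GuttmanSolver | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One majorization step of the joint two-domain objective.

    Updates both embeddings at once through the stacked-configuration trick
    described in the module docstring; the joint objective
    stress + stress' + 2λ⟨P, d²(ZO, Z')⟩ does not increase.  Returns the new
    (Z, Z') with Z expressed in its own (pre-rotation) frame.
    """
    if lam < 0:
        raise ValueError("matching penalty must be >= 0")
    n, n2 = Z.shape[0], Z_prime.shape[0]
    if lam == 0:
        # decoupled objective: two independent within-domain updates
        return smacof_step(Z, D, W), smacof_step(Z_prime, D_prime, W_prime)
    Db = np.zeros((n + n2, n + n2))
    Db[:n, :n] = D
    Db[n:, n:] = D_prime
    Wb = stacked_weights(W, W_prime, P, lam)
    X = np.vstack([Z @ O, Z_prime])
    X_new = smacof_step(X, Db, Wb, solver=solver)
    return X_new[:n] @ O.T, X_new[n:]


def stacked_weights(
    W: np.ndarray, W_prime: np.ndarray, P: np.ndarray, lam: float
) -> np.ndarray:
    """Block weight matrix [[W, λP], [λPᵀ, W']] of the stacked joint problem."""
    n, n2 = W.shape[0], W_prime.shape[0]
    Wb = np.zeros((n + n2, n + n2))
    Wb[:n, :n] = W
    Wb[n:, n:] = W_prime
    Wb[:n, n:] = lam * P
    Wb[n:, :n] = lam * P.T
    return Wb
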