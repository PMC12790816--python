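"""Entropic optimal transport (log-domain Sinkhorn) and orthogonal Procrustes.

Alternating the two solves the Wasserstein–Procrustes problem

    min_{O in O_d, P in Π(a,b)}  ⟨P, d²(ZO, Z')⟩_F − εH(P)

with the entropy convention H(P) = −Σ_ij P_ij (log P_ij − 1), under which the
Sinkhorn fixed point P = diag(u) exp(−C/ε) diag(v) is the exact optimum.
Fixing O gives entropic OT solved by Sinkhorn scaling; fixing P gives the
classic orthogonal Procrustes problem solved by the SVD of ZᵀPZ'.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.linalg import svd
from scipy.special import xlogy


def _lse(M: np.ndarray, axis: int) -> np.ndarray:
    """logsumexp specialized for 2-D dense arrays (hot path of Sinkhorn)."""
    m = M.max(axis=axis)
    return np.log(np.exp(M - np.expand_dims(m, axis)).sum(axis=axis)) + m

__all__ = [
    "SinkhornError",
    "squared_distance_cost",
    "entropy",
    "sinkhorn",
    "orthogonal_procrustes",
    "wasserstein_procrustes",
    "entropic_objective",
    "gromov_wasserstein_coupling",
]


class SinkhornError(RuntimeError):
    """Raised when Sinkhorn scaling fails to reach the marginal tolerance."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"Sinkhorn did not converge in {max_iter} iterations "
            f"(marginal residual {residual:.3e})"
        )


def squared_distance_cost(Z: np.ndarray, O: np.ndarray, Z_prime: np.ndarray) -> np.ndarray:
    """Cost matrix C[i, j] = ||z_i O − z'_j||²."""
    Z = np.asarray(Z, float)
    Z_prime = np.asarray(Z_prime, float)
    if Z.shape[1] != O.shape[0] or O.shape[1] != Z_prime.shape[1]:
        raise ValueError(
            f"dimension mismatch: Z {Z.shape}, O {O.shape}, Z' {Z_prime.shape}"
        )
    Y = Z @ O
    sq = (
        np.sum(Y**2, axis=1)[:, None]
        + np.sum(Z_prime**2, axis=1)[None, :]
        - 2.0 * Y @ Z_prime.T
    )
    return np.maximum(sq, 0.0)


def entropy(P: np.ndarray) -> float:
    """H(P) = −Σ_ij P_ij (log P_ij − 1), with 0·log 0 = 0."""
    P = np.asarray(P, float)
    return float(-np.sum(xlogy(P, P) - P))


class SinkhornResult(NamedTuple):
    plan: np.ndarray
    f: np.ndarray  # dual potential on the first marginal
    g: np.ndarray  # dual potential on the second marginal
    n_iter: int
    residual: float


def sinkhorn(
    C: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    eps: float,
    max_iter: int = 1000,
    tol: float = 1e-9,
    init_potentials: tuple[np.ndarray, np.ndarray] | None = None,
    eps_scaling: bool = True,
    round_marginals: bool = False,
) -> SinkhornResult:
    """Entropic OT plan by log-domain Sinkhorn scaling.

    Parameters
    ----------
    C : nonnegative n × n' cost matrix.
    a, b : positive marginals, each summing to 1.
    eps : entropic regularization ε > 0.
    tol : maximum absolute marginal violation accepted.
    init_potentials : optional warm-start dual potentials (f, g).
    eps_scaling : when no warm start is given, anneal ε down from the cost
        scale to the target value, carrying the dual potentials along.  This
        is the standard acceleration for small ε, where plain Sinkhorn
        converges only at a slow linear rate; the returned plan is still the
        fixed point at the target ε.
    round_marginals : project the final plan onto Π(a, b) exactly (row/column
        rescaling plus a rank-one correction), so the returned marginals hold
        to machine precision regardless of where the iteration stopped; the
        pre-rounding residual is reported in the result.  In the small-ε
        regime the raw Sinkhorn residual decays only like O(1/iterations),
        so the iterative loops of the aligner run in this mode.

    Raises
    ------
    SinkhornError if ``round_marginals`` is off and the marginal residual is
    still above ``tol`` after ``max_iter`` iterations at the target ε.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    C = np.asarray(C, float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, m = C.shape
    if a.shape != (n,) or b.shape != (m,):
        raise ValueError("marginal lengths do not match the cost matrix")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("marginals must be strictly positive")
    if not (np.isclose(a.sum(), 1.0) and np.isclose(b.sum(), 1.0)):
        raise ValueError("marginals must each sum to 1")
    log_a, log_b = np.log(a), np.log(b)
    if init_potentials is not None:
        f, g = (np.array(p, float) for p in init_potentials)
    else:
        f = np.zeros(n)
        g = np.zeros(m)
        if eps_scaling:
            cur = float(C.max())
            while cur > eps * 2.0:
                for _ in range(30):
                    f = cur * (log_a - _lse((g[None, :] - C) / cur, axis=1))
                    g = cur * (log_b - _lse((f[:, None] - C) / cur, axis=0))
                cur /= 2.0
    residual = np.inf
    for it in range(1, max_iter + 1):
        f = eps * (log_a - _lse((g[None, :] - C) / eps, axis=1))
        g = eps * (log_b - _lse((f[:, None] - C) / eps, axis=0))
        if it % 5 == 0 or it == max_iter:
            P = np.exp((f[:, None] + g[None, :] - C) / eps)
            residual = max(
                np.abs(P.sum(axis=1) - a).max(), np.abs(P.sum(axis=0) - b).max()
            )
            if residual < tol:
                if round_marginals:
                    P = _round_to_marginals(P, a, b)
                return SinkhornResult(P, f, g, it, residual)
    if round_marginals:
        P = np.exp((f[:, None] + g[None, :] - C) / eps)
        return SinkhornResult(_round_to_marginals(P, a, b), f, g, max_iter, residual)
    raise SinkhornError(residual, max_iter)


def _round_to_marginals(P: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Project an almost-feasible plan onto Π(a, b) exactly.

    Row and column sums are first scaled down where they exceed the targets,
    then the remaining mass deficit is restored by a nonnegative rank-one
    correction — the classic rounding used to certify feasibility of
    approximate Sinkhorn plans.
    """
    r = P.sum(axis=1)
    P = P * np.minimum(1.0, a / np.where(r > 0, r, 1.0))[:, None]
    c = P.sum(axis=0)
    P = P * np.minimum(1.0, b / np.where(c > 0, c, 1.0))[None, :]
    err_a = np.maximum(a - P.sum(axis=1), 0.0)  # clip float noise
    err_b = np.maximum(b - P.sum(axis=0), 0.0)
    s = err_a.sum()
    if s > 0:
        P = P + np.outer(err_a, err_b) / s
    return P


def orthogonal_procrustes(Z: np.ndarray, P: np.ndarray, Z_prime: np.ndarray) -> np.ndarray:
    """O = UVᵀ from the SVD of ZᵀPZ', the minimizer of ⟨P, d²(ZO, Z')⟩ over O_d.

    Reflections are permitted (no det(O) = +1 constraint): the feasible set is
    the full orthogonal group.
    """
    M = Z.T @ P @ Z_prime
    if not np.any(M):
        raise ValueError("degenerate all-zero cross matrix ZᵀPZ'")
    U, _, Vt = svd(M)
    return U @ Vt


def entropic_objective(P: np.ndarray, C: np.ndarray, eps: float) -> float:
    """⟨P, C⟩_F − εH(P), the objective of the entropic OT problem."""
    return float(np.sum(P * C)) - eps * entropy(P)


def gromov_wasserstein_coupling(
    D1: np.ndarray,
    D2: np.ndarray,
    eps: float = 0.001,
    max_outer: int = 50,
    tol: float = 1e-6,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
) -> np.ndarray:
    """Entropic Gromov–Wasserstein coupling between two dissimilarity matrices.

    Square-loss GW by projected mirror descent: each step linearizes the GW
    objective at the current plan (cost = constC − 2·D1·P·D2 for the square
    loss) and solves the resulting entropic OT problem by Sinkhorn.  Used to
    initialize the joint alignment with correspondences derived from global
    distance structure alone — registration is then decided before any
    embedding exists, which makes the alignment robust to the spurious
    rigid-motion optima that plague embedding-level matching.
    """
    D1 = np.asarray(D1, float)
    D2 = np.asarray(D2, float)
    n, m = D1.shape[0], D2.shape[0]
    if a is None:
        a = np.full(n, 1.0 / n)
    if b is None:
        b = np.full(m, 1.0 / m)
    P = np.outer(a, b)
    constC = (D1**2 @ a)[:, None] + (b @ D2**2)[None, :]
    pot = None
    for _ in range(max_outer):
        C = constC - 2.0 * D1 @ P @ D2
        C = np.maximum(C - C.min(), 0.0)
        sk = sinkhorn(
            C, a, b, eps, max_iter=2000, tol=1e-3,
            init_potentials=pot, round_marginals=True,
        )
        pot = (sk.f, sk.g)
        P_new = sk.plan
        if np.linalg.norm(P_new - P) < tol * np.linalg.norm(P):
            return P_new
        P = P_new
    return P


def orthogonal_candidates(d: int, n_candidates: int, seed: int = 0) -> list[np.ndarray]:
    """Candidate orthogonal initializations spanning O_d.

    For d = 2 a deterministic grid of rotations and reflected rotations (the
    two components of O_2); for higher d, Haar-distributed orthogonal
    matrices.  Always starts with the identity.
    """
    from scipy.stats import ortho_group

    cands = [np.eye(d)]
    if d == 2:
        n_angles = max(1, n_candidates // 2)
        flip = np.diag([1.0, -1.0])
        for t in np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False):
            R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            cands.extend([R, R @ flip])
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_candidates):
            cands.append(ortho_group.rvs(d, random_state=rng))
    return cands[: n_candidates + 1]


def _nn_cost(Z: np.ndarray, O: np.ndarray, Z_prime: np.ndarray) -> float:
    """Mean nearest-neighbour squared distance under a candidate rotation.

    A cheap proxy for the transport cost used to pre-select the basin of the
    alternation: the correct rigid alignment sends every point close to some
    counterpart, giving a near-zero value.
    """
    C = squared_distance_cost(Z, O, Z_prime)
    return float((C.min(axis=1).mean() + C.min(axis=0).mean()) / 2.0)


class WassersteinProcrustesResult(NamedTuple):
    coupling: np.ndarray
    transform: np.ndarray
    objective_trace: list[float]
    potentials: tuple[np.ndarray, np.ndarray]


def wasserstein_procrustes(
    Z: np.ndarray,
    Z_prime: np.ndarray,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
    eps: float = 0.01,
    n_alternations: int = 1,
    O_init: np.ndarray | None = None,
    sinkhorn_max_iter: int = 1000,
    sinkhorn_tol: float = 1e-9,
    init_potentials: tuple[np.ndarray, np.ndarray] | None = None,
    sinkhorn_round: bool = False,
    n_restarts: int = 1,
    restart_seed: int = 0,
) -> WassersteinProcrustesResult:
    """Alternate Sinkhorn (O fixed) and Procrustes (P fixed) from O = I.

    With ``n_alternations = 0`` the result is the Sinkhorn plan for the
    initial O together with that O unchanged.  The entropic objective
    ⟨P, C(O)⟩ − εH(P) is non-increasing across half-steps and is returned as
    a trace (one value after each Sinkhorn solve and each Procrustes update).

    The alternation only refines within the attraction basin of its starting
    O.  With ``n_restarts > 1`` (and no explicit ``O_init``), candidate
    orthogonal starts are screened by their nearest-neighbour transport-cost
    proxy and the alternation starts from the cheapest one.
    """
    n, m = Z.shape[0], Z_prime.shape[0]
    d = Z.shape[1]
    if a is None:
        a = np.full(n, 1.0 / n)
    if b is None:
        b = np.full(m, 1.0 / m)
    if O_init is None and n_restarts > 1:
        cands = orthogonal_candidates(d, n_restarts, seed=restart_seed)
        O = min(cands, key=lambda Oc: _nn_cost(Z, Oc, Z_prime))
    else:
        O = np.eye(d) if O_init is None else np.asarray(O_init, float)
    trace: list[float] = []
    C = squared_distance_cost(Z, O, Z_prime)
    sk = sinkhorn(
        C, a, b, eps, sinkhorn_max_iter, sinkhorn_tol,
        init_potentials=init_potentials, round_marginals=sinkhorn_round,
    )
    P = sk.plan
    trace.append(entropic_objective(P, C, eps))
    for _ in range(n_alternations):
        O_prev = O
        O = orthogonal_procrustes(Z, P, Z_prime)
        C = squared_distance_cost(Z, O, Z_prime)
        trace.append(entropic_objective(P, C, eps))
        # reuse dual potentials only while O moved little; after a large jump
        # a fresh annealed start converges far faster than a stale warm start
        warm = (sk.f, sk.g) if np.linalg.norm(O - O_prev) < 0.5 else None
        sk = sinkhorn(
            C, a, b, eps, sinkhorn_max_iter, sinkhorn_tol,
            init_potentials=warm, round_marginals=sinkhorn_round,
        )
        P = sk.plan
        trace.append(entropic_objective(P, C, eps))
    return WassersteinProcrustesResult(P, O, trace, (sk.f, sk.g))
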