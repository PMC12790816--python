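import itertools

import numpy as np
import pytest
from scipy.optimize import linprog
from scipy.stats import ortho_group

from jointmds.ot import (
    SinkhornError,
    entropic_objective,
    entropy,
    orthogonal_procrustes,
    sinkhorn,
    squared_distance_cost,
    wasserstein_procrustes,
)


def uniform(n):
    return np.full(n, 1.0 / n)


class TestCost:
    def test_rotated_copy_has_zero_diagonal(self, rng):
        Z = rng.standard_normal((5, 2))
        th = 0.4
        O = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        C = squared_distance_cost(Z, O, Z @ O)
        np.testing.assert_allclose(np.diag(C), 0.0, atol=1e-12)

    def test_one_dimensional_hand_case(self):
        Z = np.array([[0.0], [2.0]])
        C = squared_distance_cost(Z, np.eye(1), Z[::-1])
        np.testing.assert_allclose(C, [[4.0, 0.0], [0.0, 4.0]])

    def test_matches_brute_force(self, rng):
        Z = rng.standard_normal((3, 2))
        Zp = rng.standard_normal((4, 2))
        O = ortho_group.rvs(2, random_state=rng)
        C = squared_distance_cost(Z, O, Zp)
        for i in range(3):
            for j in range(4):
                assert C[i, j] == pytest.approx(
                    np.sum((Z[i] @ O - Zp[j]) ** 2), abs=1e-12
                )

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            squared_distance_cost(
                rng.standard_normal((3, 2)), np.eye(2), rng.standard_normal((3, 3))
            )


class TestEntropy:
    def test_uniform_coupling_closed_form(self):
        n, m = 3, 4
        P = np.full((n, m), 1.0 / (n * m))
        assert entropy(P) == pytest.approx(np.log(n * m) + 1.0)

    def test_permutation_coupling(self):
        P = np.eye(2) / 2.0
        assert entropy(P) == pytest.approx(np.log(2) + 1.0)

    def test_uniform_maximizes(self, rng):
        for _ in range(10):
            P = rng.uniform(size=(3, 3))
            P /= P.sum()
            assert entropy(P) <= entropy(np.full((3, 3), 1.0 / 9)) + 1e-12


class TestSinkhorn:
    def test_constant_cost_gives_product_coupling(self):
        C = np.full((3, 4), 2.0)
        res = sinkhorn(C, uniform(3), uniform(4), eps=0.5)
        np.testing.assert_allclose(res.plan, np.outer(uniform(3), uniform(4)), atol=1e-8)

    def test_small_eps_recovers_assignment(self):
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = sinkhorn(C, uniform(2), uniform(2), eps=0.01)
        np.testing.assert_allclose(res.plan, np.eye(2) / 2.0, atol=1e-4)

    def test_marginals_conserved_on_random_instances(self, rng):
        for _ in range(100):
            n, m = rng.integers(2, 6, size=2)
            C = rng.uniform(size=(n, m))
            res = sinkhorn(C, uniform(n), uniform(m), eps=0.1, tol=1e-9)
            assert np.abs(res.plan.sum(axis=1) - uniform(n)).max() < 1e-6
            assert np.abs(res.plan.sum(axis=0) - uniform(m)).max() < 1e-6

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_objective_matches_convex_solver(self, rng):
        """The entropic objective at the Sinkhorn plan must match an
        independent convex solve over the transport polytope."""
        from scipy.optimize import LinearConstraint, minimize

        n = 3
        C = rng.uniform(size=(n, n))
        eps = 0.1
        res = sinkhorn(C, uniform(n), uniform(n), eps=eps, tol=1e-12, max_iter=20000)
        ours = entropic_objective(res.plan, C, eps)

        def obj(x):
            P = np.abs(x.reshape(n, n))
            return float((P * C).sum()) - eps * entropy(P)

        A = np.zeros((2 * n, n * n))
        for i in range(n):
            A[i, i * n : (i + 1) * n] = 1.0
        for j in range(n):
            A[n + j, j::n] = 1.0
        sol = minimize(
            obj, np.full(n * n, 1.0 / n**2), method="trust-constr",
            constraints=[LinearConstraint(A, 1.0 / n, 1.0 / n)],
            bounds=[(1e-12, 1.0)] * (n * n),
            options={"maxiter": 3000, "gtol": 1e-12, "xtol": 1e-14},
        )
        assert ours == pytest.approx(sol.fun, abs=1e-6)

    def test_small_eps_matches_lp_assignment(self, rng):
        """As eps -> 0 the plan approaches the optimal-transport LP solution,
        checked against brute-force enumeration of permutation couplings."""
        for n in (2, 3, 4):
            C = rng.uniform(size=(n, n))
            res = sinkhorn(C, uniform(n), uniform(n), eps=0.002, tol=1e-7,
                           max_iter=50000)
            got = float((res.plan * C).sum())
            best = min(
                sum(C[i, p[i]] for i in range(n)) / n
                for p in itertools.permutations(range(n))
            )
            assert got == pytest.approx(best, abs=1e-3)

    def test_nonconvergence_raises_with_residual(self, rng):
        C = rng.uniform(size=(4, 4))
        with pytest.raises(SinkhornError) as exc:
            sinkhorn(C, uniform(4), uniform(4), eps=1e-4, max_iter=1,
                     eps_scaling=False)
        assert exc.value.residual > 0

    def test_invalid_eps(self):
        with pytest.raises(ValueError):
            sinkhorn(np.eye(2), uniform(2), uniform(2), eps=0.0)


class TestProcrustes:
    def test_identity_recovered(self, rng):
        Z = rng.standard_normal((6, 3))
        O = orthogonal_procrustes(Z, np.eye(6) / 6, Z)
        np.testing.assert_allclose(O, np.eye(3), atol=1e-10)

    def test_planted_rotation_recovered(self, rng):
        Z = rng.standard_normal((10, 2))
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        O = orthogonal_procrustes(Z, np.eye(10) / 10, Z @ R)
        np.testing.assert_allclose(O, R, atol=1e-8)

    def test_output_always_orthogonal(self, rng):
        for _ in range(10):
            Z = rng.standard_normal((5, 3))
            Zp = rng.standard_normal((5, 3))
            P = rng.uniform(size=(5, 5))
            P /= P.sum()
            O = orthogonal_procrustes(Z, P, Zp)
            np.testing.assert_allclose(O.T @ O, np.eye(3), atol=1e-8)

    def test_degenerate_cross_matrix(self):
        Z = np.zeros((3, 2))
        with pytest.raises(ValueError, match="degenerate"):
            orthogonal_procrustes(Z, np.eye(3) / 3, Z)


class TestWassersteinProcrustes:
    def test_zero_alternations_returns_initial_transform(self, rng):
        Z = rng.standard_normal((5, 2))
        Zp = rng.standard_normal((5, 2))
        res = wasserstein_procrustes(Z, Zp, eps=0.5, n_alternations=0)
        np.testing.assert_array_equal(res.transform, np.eye(2))
        expected = sinkhorn(
            squared_distance_cost(Z, np.eye(2), Zp), uniform(5), uniform(5), eps=0.5
        ).plan
        np.testing.assert_allclose(res.coupling, expected, atol=1e-12)

    def test_planted_rotation_recovered_with_restarts(self, rng):
        Z = rng.standard_normal((40, 2))
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        res = wasserstein_procrustes(
            Z, Z @ R, eps=1e-3, n_alternations=20, n_restarts=24,
            sinkhorn_max_iter=3000, sinkhorn_tol=1e-3, sinkhorn_round=True,
        )
        assert np.trace(res.coupling) > 0.9
        np.testing.assert_allclose(res.transform, R, atol=1e-3)

    def test_identical_embeddings_give_diagonal_coupling(self, rng):
        Z = rng.standard_normal((30, 2))
        res = wasserstein_procrustes(
            Z, Z, eps=1e-3, n_alternations=10, n_restarts=24,
            sinkhorn_max_iter=3000, sinkhorn_tol=1e-3, sinkhorn_round=True,
        )
        assert np.trace(res.coupling) > 0.9

    def test_objective_trace_non_increasing(self, rng):
        Z = rng.standard_normal((15, 2))
        Zp = rng.standard_normal((15, 2))
        res = wasserstein_procrustes(Z, Zp, eps=0.5, n_alternations=10,
                                     sinkhorn_tol=1e-9, sinkhorn_max_iter=20000)
        tr = res.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(tr, tr[1:]))
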