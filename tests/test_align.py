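import numpy as np
import pytest
from scipy.spatial.distance import cdist

from jointmds.align import (
    Hyperparams,
    apply_alignment,
    grid_search,
    joint_mds,
    joint_mds3,
)
from jointmds.dissimilarity import (
    geodesic_distances,
    normalize_dissimilarity,
    pairwise_euclidean,
)
from jointmds.evaluation import foscttm
from jointmds.smacof import init_embedding, uniform_weights, weighted_mds
from tests.conftest import random_dissimilarity


class TestJointMds:
    def test_self_alignment_recovers_matches(self, gaussian_geodesic):
        res = joint_mds(
            gaussian_geodesic, gaussian_geodesic, d=2, lam=10.0, eps=0.001, seed=1
        )
        assert foscttm(res.Z, res.Z_prime) < 0.05

    def test_same_seed_bitwise_identical(self, gaussian_geodesic):
        r1 = joint_mds(gaussian_geodesic, gaussian_geodesic, d=2, lam=1.0,
                       eps=0.01, seed=3, max_outer=10)
        r2 = joint_mds(gaussian_geodesic, gaussian_geodesic, d=2, lam=1.0,
                       eps=0.01, seed=3, max_outer=10)
        np.testing.assert_array_equal(r1.Z, r2.Z)
        np.testing.assert_array_equal(r1.Z_prime, r2.Z_prime)
        np.testing.assert_array_equal(r1.P, r2.P)

    def test_lambda_zero_decouples_domains(self, rng):
        """With no matching penalty the embeddings solve the two independent
        MDS problems: the coupling P has no influence on the geometry."""
        D1 = random_dissimilarity(rng, 12)
        D2 = random_dissimilarity(rng, 12)
        res = joint_mds(D1, D2, d=2, lam=0.0, eps=0.01, seed=5, max_outer=5)
        # same per-domain stress as an independent SMACOF run from the same
        # starting configuration (rotation by O does not change distances)
        ss = np.random.SeedSequence(5)
        s1, s2 = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
        ref1 = weighted_mds(D1, None, 2, init_embedding(12, 2, s1)).embedding
        ref2 = weighted_mds(D2, None, 2, init_embedding(12, 2, s2)).embedding
        # the joint run continues refining, so distances agree only loosely
        np.testing.assert_allclose(cdist(res.Z, res.Z), cdist(ref1, ref1), atol=0.05)
        np.testing.assert_allclose(
            cdist(res.Z_prime, res.Z_prime), cdist(ref2, ref2), atol=0.05
        )

    def test_trace_monotone_without_annealing(self, rng):
        D1 = random_dissimilarity(rng, 10)
        D2 = random_dissimilarity(rng, 10)
        res = joint_mds(D1, D2, d=2, lam=1.0, eps=0.05, seed=0, max_outer=30,
                        eps_annealing=False, sinkhorn_tol=1e-6)
        tr = np.array(res.trace)
        assert ((tr[1:] - tr[:-1]) <= 1e-6 * np.abs(tr[:-1]) + 1e-9).all()

    def test_invalid_parameters(self, rng):
        D = random_dissimilarity(rng, 5)
        with pytest.raises(ValueError):
            joint_mds(D, D, lam=-1.0)
        with pytest.raises(ValueError):
            joint_mds(D, D, eps=0.0)

    def test_coupling_is_valid_transport_plan(self, gaussian_geodesic):
        res = joint_mds(gaussian_geodesic, gaussian_geodesic, d=2, lam=1.0,
                        eps=0.01, seed=0, max_outer=15)
        n = gaussian_geodesic.shape[0]
        assert (res.P >= 0).all()
        np.testing.assert_allclose(res.P.sum(axis=1), np.full(n, 1 / n), atol=1e-6)
        np.testing.assert_allclose(res.P.sum(axis=0), np.full(n, 1 / n), atol=1e-6)


class TestApplyAlignment:
    def test_identity_is_noop(self, rng):
        Z = rng.standard_normal((5, 2))
        np.testing.assert_array_equal(apply_alignment(Z, np.eye(2), "first"), Z)

    def test_rotation_preserves_pairwise_distances(self, rng):
        Z = rng.standard_normal((8, 2))
        th = 0.9
        O = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        Z2 = apply_alignment(Z, O, "first")
        np.testing.assert_allclose(cdist(Z2, Z2), cdist(Z, Z), atol=1e-12)

    def test_second_side_is_reference_frame(self, rng):
        Z = rng.standard_normal((5, 2))
        np.testing.assert_array_equal(apply_alignment(Z, np.eye(2), "second"), Z)

    def test_unknown_side_rejected(self, rng):
        with pytest.raises(ValueError, match="side"):
            apply_alignment(rng.standard_normal((3, 2)), np.eye(2), "third")


class TestJointMds3:
    def test_three_identical_domains_align(self, gaussian_geodesic):
        params = Hyperparams(k=5, eps=0.001, lam=10.0, d=2)
        res = joint_mds3(
            gaussian_geodesic, gaussian_geodesic, gaussian_geodesic,
            core=1, params=params, seed=0,
        )
        pair_scores = [
            foscttm(res.Z1, res.Z2), foscttm(res.Z1, res.Z3), foscttm(res.Z2, res.Z3)
        ]
        assert np.mean(pair_scores) < 0.05

    def test_unequal_sample_counts_rejected(self, rng):
        D1 = random_dissimilarity(rng, 6)
        D2 = random_dissimilarity(rng, 5)
        with pytest.raises(ValueError, match="same sample count"):
            joint_mds3(D1, D1, D2)

    @pytest.mark.parametrize("core", [1, 2, 3])
    def test_any_core_yields_common_dimension(self, rng, core):
        D = [random_dissimilarity(rng, 8) for _ in range(3)]
        res = joint_mds3(*D, core=core, params=Hyperparams(d=2), seed=0,
                         max_outer=5)
        assert res.core == core
        assert {Z.shape for Z in res.embeddings} == {(8, 2)}

    def test_final_transforms_are_isometries(self, rng):
        """The merge and carry-over steps only rotate finished embeddings:
        within-domain distance matrices of the satellites are preserved."""
        D = [random_dissimilarity(rng, 8) for _ in range(3)]
        res = joint_mds3(*D, core=1, params=Hyperparams(d=2), seed=2, max_outer=5)
        r_ab = res.pairwise["core_b"]
        r_ac = res.pairwise["core_c"]
        np.testing.assert_allclose(
            cdist(res.Z2, res.Z2), cdist(r_ab.Z_prime, r_ab.Z_prime), atol=1e-9
        )
        np.testing.assert_allclose(
            cdist(res.Z3, res.Z3), cdist(r_ac.Z_prime, r_ac.Z_prime), atol=1e-9
        )

    def test_deterministic(self, rng):
        D = [random_dissimilarity(rng, 8) for _ in range(3)]
        r1 = joint_mds3(*D, params=Hyperparams(d=2), seed=4, max_outer=5)
        r2 = joint_mds3(*D, params=Hyperparams(d=2), seed=4, max_outer=5)
        for Za, Zb in zip(r1.embeddings, r2.embeddings):
            np.testing.assert_array_equal(Za, Zb)


class TestGridSearch:
    def test_single_cell_returned(self, gaussian_cloud):
        E = pairwise_euclidean(gaussian_cloud)
        best, table = grid_search(E, E, [5], [0.01], [1.0], n_seeds=1,
                                  max_outer=5)
        assert (best.k, best.eps, best.lam) == (5, 0.01, 1.0)
        assert len(table) == 1

    def test_two_cells_better_one_wins(self, gaussian_cloud):
        """A matching penalty of zero cannot align the domains, so the
        lambda > 0 cell must score a lower FOSCTTM."""
        E = pairwise_euclidean(gaussian_cloud)
        best, table = grid_search(E, E, [5], [0.001], [0.0, 10.0], n_seeds=1,
                                  max_outer=40)
        assert best.lam == 10.0
        scores = table.set_index("lam")["score"]
        assert scores[10.0] < scores[0.0]

    def test_tie_breaks_lexicographically(self, gaussian_cloud, monkeypatch):
        import jointmds.align as al

        E = pairwise_euclidean(gaussian_cloud)
        monkeypatch.setattr(
            al, "joint_mds",
            lambda *a, **k: al.JointMDSResult(
                Z=np.zeros((50, 2)), Z_prime=np.zeros((50, 2)),
                P=np.eye(50) / 50, O=np.eye(2), objective=[1.0],
            ),
        )
        monkeypatch.setattr("jointmds.evaluation.foscttm", lambda Z, Zp: 0.5)
        best, _ = grid_search(E, E, [5, 3], [0.01, 0.001], [2.0, 1.0], n_seeds=1)
        assert (best.k, best.eps, best.lam) == (3, 0.001, 1.0)

    def test_empty_grid_rejected(self, gaussian_cloud):
        E = pairwise_euclidean(gaussian_cloud)
        with pytest.raises(ValueError, match="non-empty"):
            grid_search(E, E, [], [0.01], [1.0])


class TestGridSearch3:
    def test_single_cell_and_score_range(self, gaussian_cloud):
        from jointmds.align import grid_search3

        E = pairwise_euclidean(gaussian_cloud)
        best, table = grid_search3(E, E, E, [5], [0.001], [1.0], d=2,
                                   n_seeds=1, max_outer=20)
        assert (best.k, best.eps, best.lam) == (5, 0.001, 1.0)
        assert 0.0 <= table["score"].iloc[0] <= 1.0

    def test_uncoupled_cell_loses(self, gaussian_cloud):
        from jointmds.align import grid_search3

        E = pairwise_euclidean(gaussian_cloud)
        best, table = grid_search3(E, E, E, [5], [0.001], [0.0, 1.0], d=2,
                                   n_seeds=1, max_outer=30)
        assert best.lam == 1.0
        scores = table.set_index("lam")["score"]
        assert scores[1.0] < scores[0.0]
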