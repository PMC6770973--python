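import numpy as np
import pytest

from dmapred import (
    AssociationMatrix,
    Hyperparameters,
    SimilarityMatrix,
    fit,
    initialize_factors,
    objective,
    rank_candidates,
)
from dmapred.knn import build_neighbor_graph, symmetrize_and_degree
from dmapred.model import (
    FactorSet,
    update_C,
    update_H,
    update_U,
    update_W,
    update_X,
    update_cycle,
)

from conftest import random_problem
from oracles import loop_objective


def zero_graph(nm):
    return symmetrize_and_degree(np.zeros((nm, nm)))


class TestInitializeFactors:
    def test_deterministic_for_seed(self):
        a = initialize_factors(5, 4, 3, seed=11)
        b = initialize_factors(5, 4, 3, seed=11)
        for Za, Zb in zip((a.U, a.W, a.H, a.X, a.C), (b.U, b.W, b.H, b.X, b.C)):
            assert np.array_equal(Za, Zb)

    def test_strictly_positive(self):
        f = initialize_factors(6, 5, 4, seed=0)
        assert min(Z.min() for Z in (f.U, f.W, f.H, f.X, f.C)) > 0

    def test_corpus_scale_shapes(self):
        f = initialize_factors(490, 326, 100, seed=0)
        assert f.U.shape == (490, 326)
        assert f.H.shape == (100, 490)
        assert f.X.shape == (326, 100)


class TestObjective:
    def test_perfect_reconstruction_zero(self):
        # all weights zero except the M term; W, H exact factors of M
        rng = np.random.default_rng(0)
        W = rng.uniform(0.1, 1, (5, 2))
        H = rng.uniform(0.1, 1, (2, 5))
        p = Hyperparameters(alpha=0, beta=0, lam=0, delta=0, eta=0, k_latent=2)
        f = FactorSet(U=np.zeros((5, 3)), W=W, H=H, X=np.ones((3, 2)), C=np.ones((2, 3)))
        F, _ = objective(f, W @ H, np.zeros((3, 3)), np.zeros((5, 3)), zero_graph(5), p)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_coupled_zero_configuration(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(0.1, 1, (4, 2))
        H = rng.uniform(0.1, 1, (2, 4))
        X = rng.uniform(0.1, 1, (3, 2))
        C = rng.uniform(0.1, 1, (2, 3))
        f = FactorSet(U=H.T @ C, W=W, H=H, X=X, C=C)
        p = Hyperparameters(alpha=1.0, beta=0, lam=1.0, delta=0, eta=0, k_latent=2)
        F, _ = objective(f, W @ H, X @ C, np.zeros((4, 3)), zero_graph(4), p)
        assert F == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_loop_oracle(self, seed):
        M, D, A = random_problem(seed, nm=6, nd=4)
        rng = np.random.default_rng(seed + 100)
        p = Hyperparameters(
            alpha=rng.uniform(0, 2), beta=rng.uniform(0, 2), lam=rng.uniform(0, 2),
            delta=rng.uniform(0, 2), eta=rng.uniform(0, 2), k_latent=3, k_neighbors=2,
        )
        f = initialize_factors(6, 4, 3, seed)
        g = build_neighbor_graph(M, 2)
        F, _ = objective(f, M, D, A, g, p)
        assert F == pytest.approx(loop_objective(f, M, D, A, g, p), rel=1e-12)


class TestUpdateU:
    def test_hand_solved_fixed_point(self):
        # eta=0, delta=0, beta=lam=1, all pairs observed: stationarity gives
        # U = (A + H.T C) / 2; iterating update_U from any start must reach it
        rng = np.random.default_rng(5)
        A = np.ones((3, 2))
        H = rng.uniform(0.1, 1, (2, 3))
        C = rng.uniform(0.1, 1, (2, 2))
        p = Hyperparameters(beta=1, lam=1, delta=0, eta=0, k_latent=2)
        f = FactorSet(U=rng.uniform(0.1, 1, (3, 2)), W=np.ones((3, 2)), H=H,
                      X=np.ones((2, 2)), C=C)
        g = zero_graph(3)
        for _ in range(200):
            f.U = update_U(f, A, g, p)
        assert np.allclose(f.U, (A + H.T @ C) / 2, atol=1e-10)

    def test_fixed_point_preserved(self):
        rng = np.random.default_rng(6)
        A = np.ones((3, 2))
        H = rng.uniform(0.1, 1, (2, 3))
        C = rng.uniform(0.1, 1, (2, 2))
        p = Hyperparameters(beta=1, lam=1, delta=0, eta=0, k_latent=2)
        U_star = (A + H.T @ C) / 2
        f = FactorSet(U=U_star.copy(), W=np.ones((3, 2)), H=H, X=np.ones((2, 2)), C=C)
        assert np.allclose(update_U(f, A, zero_graph(3), p), U_star, atol=1e-12)

    def test_consistent_update_does_not_increase_objective(self, small_problem, small_graph):
        M, D, A = small_problem
        p = Hyperparameters(k_latent=4, k_neighbors=3)
        f = initialize_factors(M.n, D.n, 4, seed=3)
        before, _ = objective(f, M, D, A, small_graph, p)
        f.U = update_U(f, A, small_graph, p)
        after, _ = objective(f, M, D, A, small_graph, p)
        assert after <= before + 1e-9 * abs(before)


class TestUpdateHWXC:
    def test_h_reduces_to_lee_seung_without_coupling(self):
        rng = np.random.default_rng(7)
        M = rng.uniform(0.1, 1, (5, 5))
        M = (M + M.T) / 2
        f = initialize_factors(5, 4, 3, seed=1)
        p = Hyperparameters(lam=0, k_latent=3)
        expected = f.H * (f.W.T @ M) / (f.W.T @ f.W @ f.H)
        assert np.allclose(update_H(f, M, p), expected, rtol=1e-12)

    def test_c_reduces_to_lee_seung_without_coupling(self):
        rng = np.random.default_rng(8)
        D = rng.uniform(0.1, 1, (4, 4))
        D = (D + D.T) / 2
        f = initialize_factors(5, 4, 3, seed=2)
        p = Hyperparameters(lam=0, alpha=0.7, k_latent=3)
        expected = f.C * (f.X.T @ D) / (f.X.T @ f.X @ f.C)
        assert np.allclose(update_C(f, D, p), expected, rtol=1e-12)

    def test_w_with_identity_h_converges_to_m(self):
        rng = np.random.default_rng(9)
        M = rng.uniform(0.1, 1, (4, 4))
        M = (M + M.T) / 2
        f = initialize_factors(4, 3, 4, seed=3)
        f.H = np.eye(4)
        for _ in range(500):
            f.W = update_W(f, M)
        assert np.allclose(f.W, M, atol=1e-8)

    def test_w_fixed_point_preserved(self):
        rng = np.random.default_rng(10)
        M = rng.uniform(0.1, 1, (4, 4))
        f = initialize_factors(4, 3, 4, seed=4)
        f.H, f.W = np.eye(4), M.copy()
        assert np.allclose(update_W(f, M), M, rtol=1e-12)

    def test_x_mirrors_w_reconstruction_descent(self):
        rng = np.random.default_rng(11)
        D = rng.uniform(0.1, 1, (8, 8))
        D = (D + D.T) / 2
        f = initialize_factors(9, 8, 4, seed=5)
        errors = []
        for _ in range(50):
            f.X = update_X(f, D)
            f.C = update_C(f, D, Hyperparameters(lam=0, alpha=1.0, k_latent=4))
            errors.append(np.sum((D - f.X @ f.C) ** 2))
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_c_alpha_zero_drives_coupling_down(self, small_problem):
        M, D, A = small_problem
        f = initialize_factors(M.n, D.n, 4, seed=6)
        p = Hyperparameters(alpha=0, lam=1.0, k_latent=4)
        before = np.sum((f.U - f.H.T @ f.C) ** 2)
        for _ in range(100):
            f.C = update_C(f, D, p)
        assert np.sum((f.U - f.H.T @ f.C) ** 2) < before

    def test_full_cycle_does_not_increase_objective(self, small_problem, small_graph):
        M, D, A = small_problem
        p = Hyperparameters(k_latent=4, k_neighbors=3)
        f = initialize_factors(M.n, D.n, 4, seed=8)
        before, _ = objective(f, M, D, A, small_graph, p)
        update_cycle(f, M, D, A, small_graph, p)
        after, _ = objective(f, M, D, A, small_graph, p)
        assert after <= before + 1e-9 * abs(before)


class TestFit:
    def test_max_iter_zero_returns_initial(self, small_problem):
        M, D, A = small_problem
        p = Hyperparameters(k_latent=4, k_neighbors=3, max_iter=0)
        f, trace = fit(M, D, A, p)
        assert trace.n_iter == 0
        assert len(trace.objective_values) == 1
        assert np.array_equal(f.U, initialize_factors(M.n, D.n, 4, p.seed).U)

    def test_deterministic_for_seed(self, small_problem):
        M, D, A = small_problem
        p = Hyperparameters(k_latent=4, k_neighbors=3, max_iter=25, seed=9)
        U1 = fit(M, D, A, p)[0].U
        U2 = fit(M, D, A, p)[0].U
        assert np.array_equal(U1, U2)

    def test_label_misalignment_rejected(self, small_problem):
        M, D, A = small_problem
        bad = AssociationMatrix(list(reversed(A.mirna_labels)), A.disease_labels, A.values)
        with pytest.raises(ValueError, match="labels"):
            fit(M, D, bad, Hyperparameters(k_latent=4, k_neighbors=3, max_iter=1))

    def test_literal_and_consistent_coincide_when_rules_match(self):
        # with alpha=1 (H weight equal), beta=1, delta=0 and every pair
        # observed (Y all ones), the published rules equal the derived ones
        rng = np.random.default_rng(12)
        labels_m = [f"m{i}" for i in range(6)]
        labels_d = [f"d{j}" for j in range(4)]
        raw = rng.uniform(size=(6, 6))
        M = SimilarityMatrix(labels_m, np.clip((raw + raw.T) / 2, 0, 1))
        raw = rng.uniform(size=(4, 4))
        D = SimilarityMatrix(labels_d, np.clip((raw + raw.T) / 2, 0, 1))
        A = AssociationMatrix(labels_m, labels_d, np.ones((6, 4)))
        base = dict(alpha=1.0, beta=1.0, delta=0.0, k_latent=3, k_neighbors=2,
                    max_iter=20, seed=4)
        U_lit = fit(M, D, A, Hyperparameters(update_mode="literal", **base))[0].U
        U_con = fit(M, D, A, Hyperparameters(update_mode="consistent", **base))[0].U
        assert np.allclose(U_lit, U_con, rtol=1e-12)

    def test_trace_monotone_on_planted_instance(self):
        from dmapred import generate

        inst = generate(30, 20, 3, 0.08, 0.1, 0.05, seed=0)
        p = Hyperparameters(k_latent=6, max_iter=150, rel_tol=1e-6)
        _, trace = fit(inst.M, inst.D, inst.A_observed, p)
        vals = trace.objective_values
        assert all(b <= a + 1e-9 * abs(a) for a, b in zip(vals, vals[1:]))


class TestNonNegativity:
    def test_random_update_sequences_stay_non_negative(self, small_problem, small_graph):
        M, D, A = small_problem
        rng = np.random.default_rng(20)
        p_pool = [
            Hyperparameters(alpha=a, beta=b, lam=l, delta=d, eta=e, k_latent=4, k_neighbors=3)
            for a, b, l, d, e in rng.uniform(0, 4, size=(10, 5))
        ]
        updates = {
            "U": lambda f, p: setattr(f, "U", update_U(f, A, small_graph, p)),
            "H": lambda f, p: setattr(f, "H", update_H(f, M, p)),
            "W": lambda f, p: setattr(f, "W", update_W(f, M)),
            "X": lambda f, p: setattr(f, "X", update_X(f, D)),
            "C": lambda f, p: setattr(f, "C", update_C(f, D, p)),
        }
        names = list(updates)
        for trial in range(40):
            p = p_pool[trial % len(p_pool)]
            f = initialize_factors(M.n, D.n, 4, seed=trial)
            for step in rng.choice(names, size=12):
                updates[step](f, p)
            assert min(Z.min() for Z in (f.U, f.W, f.H, f.X, f.C)) >= 0


class TestRankCandidates:
    def make_assoc(self, A_vals):
        nm, nd = np.shape(A_vals)
        return AssociationMatrix([f"m{i+1}" for i in range(nm)],
                                 [f"d{j+1}" for j in range(nd)], A_vals)

    def test_descending_order(self):
        A = self.make_assoc(np.zeros((3, 1)))
        U = np.array([[0.1], [0.9], [0.5]])
        assert [m for m, _ in rank_candidates(U, A, "d1")] == ["m2", "m3", "m1"]

    def test_exclude_known(self):
        A = self.make_assoc([[0], [0], [1]])
        U = np.array([[0.1], [0.9], [0.5]])
        assert [m for m, _ in rank_candidates(U, A, "d1", exclude_known=True)] == ["m2", "m1"]
        assert [m for m, _ in rank_candidates(U, A, "d1", exclude_known=False)] == ["m2", "m3", "m1"]

    def test_all_equal_scores_keep_label_order(self):
        A = self.make_assoc(np.zeros((4, 1)))
        U = np.full((4, 1), 0.5)
        assert [m for m, _ in rank_candidates(U, A, "d1")] == ["m1", "m2", "m3", "m4"]

    def test_unknown_disease_rejected(self):
        A = self.make_assoc(np.zeros((2, 1)))
        with pytest.raises(KeyError, match="nope"):
            rank_candidates(np.zeros((2, 1)), A, "nope")
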