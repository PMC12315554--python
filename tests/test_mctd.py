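import numpy as np
import pytest

from convntc import SimilarityMatrix
from convntc.data_model import IncompleteTensor
from convntc.mctd import (ADMMState, FactorSet, MCTDHyperparams,
                          augmented_lagrangian, block_update,
                          cg_solve_projection, impute, khatri_rao, laplacian,
                          matricize, mctd_fit, reconstruct_cp, row_weight,
                          update_multipliers)

from conftest import random_similarity


def loop_reconstruct(M, C, D):
    """Brute-force triple-loop CP reconstruction oracle."""
    n1, r = M.shape
    n2, n3 = C.shape[0], D.shape[0]
    T = np.zeros((n1, n2, n3))
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                T[i, j, k] = sum(M[i, l] * C[j, l] * D[k, l] for l in range(r))
    return T


def make_state(rng, nA=6, nB=4, r=2, penalties=1.0):
    Sm = random_similarity(rng, nA)
    Sd = random_similarity(rng, nB)
    sym = lambda B: 0.5 * (B + B.T)
    f = FactorSet(M=rng.uniform(size=(nA, r)), C=rng.uniform(size=(nA, r)),
                  D=rng.uniform(size=(nB, r)),
                  A_m=sym(rng.uniform(size=(r, r))),
                  A_d=sym(rng.uniform(size=(r, r))))
    st = ADMMState(
        factors=f, H=rng.uniform(size=(nA, r)), Z=rng.uniform(size=(nA, r)),
        P=rng.uniform(size=(nB, r)), F=rng.uniform(size=(nB, r)),
        Y1=rng.uniform(size=(nA, r)), Y2=rng.uniform(size=(nA, r)),
        Y3=rng.uniform(size=(nB, r)), R1=rng.uniform(size=(nA, r)),
        R2=rng.uniform(size=(nB, r)),
        rho1=penalties, rho2=penalties, rho3=penalties,
        theta1=penalties, theta2=penalties,
        X_hat=rng.uniform(size=(nA, nA, nB)), U=laplacian(Sm), V=laplacian(Sd))
    return st, Sm, Sd


def numeric_block_gradient(block, new, st, hp, Sm, Sd, eps=1e-5):
    """Central-difference gradient of the augmented Lagrangian at ``new``."""
    Wm = row_weight(st.factors.M, hp.l21_convention)
    Wd = row_weight(st.factors.D, hp.l21_convention)
    g = np.zeros_like(new)
    it = np.nditer(new, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = new[idx]
        new[idx] = orig + eps
        lp = augmented_lagrangian(st, hp, Sm, Sd, W_m=Wm, W_d=Wd,
                                  overrides={block: new})
        new[idx] = orig - eps
        lm = augmented_lagrangian(st, hp, Sm, Sd, W_m=Wm, W_d=Wd,
                                  overrides={block: new})
        new[idx] = orig
        g[idx] = (lp - lm) / (2 * eps)
        it.iternext()
    return g


class TestLaplacian:
    def test_two_node_graph(self):
        L = laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.array_equal(L, [[1.0, -1.0], [-1.0, 1.0]])

    def test_zero_graph(self):
        assert np.array_equal(laplacian(np.zeros((3, 3))), np.zeros((3, 3)))

    def test_quadratic_form_oracle(self):
        rng = np.random.default_rng(1)
        S = random_similarity(rng, 5).values
        L = laplacian(S)
        for _ in range(10):
            x = rng.standard_normal(5)
            quad = x @ L @ x
            pairwise = 0.5 * sum(S[a, b] * (x[a] - x[b]) ** 2
                                 for a in range(5) for b in range(5))
            assert quad == pytest.approx(pairwise, rel=1e-10, abs=1e-12)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(2)
        L = laplacian(random_similarity(rng, 6))
        assert np.allclose(L.sum(axis=1), 0.0, atol=1e-12)


class TestUnfoldingIdentities:
    def test_zero_tensor_any_mode(self):
        Z = np.zeros((2, 2, 2))
        for mode in (1, 2, 3):
            assert matricize(Z, mode).shape == (2, 4)
            assert not matricize(Z, mode).any()

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            matricize(np.zeros((2, 2, 2)), 4)

    def test_unfolding_is_a_bijection(self):
        rng = np.random.default_rng(0)
        T = rng.uniform(size=(3, 4, 2))
        for mode in (1, 2, 3):
            assert sorted(matricize(T, mode).ravel()) == sorted(T.ravel())

    @pytest.mark.parametrize("mode,factor_order", [
        (1, ("M", "C", "D")), (2, ("C", "M", "D")), (3, ("D", "M", "C"))])
    def test_three_factorization_identities(self, mode, factor_order):
        # matricize([[M,C,D]], n) == F_n kr(other, other)^T under the
        # module's fixed fiber ordering, against the triple-loop oracle
        rng = np.random.default_rng(5)
        M, C = rng.uniform(size=(2, 4, 2)) * 1.0, None
        M = rng.uniform(size=(4, 2))
        C = rng.uniform(size=(4, 2))
        D = rng.uniform(size=(3, 2))
        fac = {"M": M, "C": C, "D": D}
        T = loop_reconstruct(M, C, D)
        lead, a, b = (fac[n] for n in factor_order)
        assert np.allclose(matricize(T, mode), lead @ khatri_rao(a, b).T,
                           atol=1e-12)


class TestKhatriRao:
    def test_unit_vectors(self):
        A = np.array([[1.0], [0.0]])
        assert np.array_equal(khatri_rao(A, A), [[1.0], [0.0], [0.0], [0.0]])

    def test_gram_identity(self):
        rng = np.random.default_rng(3)
        A, B = rng.uniform(size=(3, 2)), rng.uniform(size=(3, 2))
        K = khatri_rao(A, B)
        assert np.allclose(K.T @ K, (A.T @ A) * (B.T @ B), atol=1e-12)

    def test_single_column_is_kronecker(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(size=(3, 1)), rng.uniform(size=(4, 1))
        assert np.allclose(khatri_rao(a, b).ravel(), np.kron(a.ravel(), b.ravel()))

    def test_column_mismatch_rejected(self):
        with pytest.raises(ValueError):
            khatri_rao(np.ones((2, 2)), np.ones((2, 3)))


class TestReconstruct:
    def test_rank_one_product(self):
        v = np.array([[1.0], [2.0]])
        T = reconstruct_cp(v, v, v)
        assert T[1, 1, 1] == 8.0

    def test_zero_factor_gives_zero_tensor(self):
        rng = np.random.default_rng(0)
        T = reconstruct_cp(np.zeros((3, 2)), rng.uniform(size=(3, 2)),
                           rng.uniform(size=(2, 2)))
        assert not T.any()

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(6)
        M, C = rng.uniform(size=(3, 3)), rng.uniform(size=(3, 3))
        D = rng.uniform(size=(2, 3))
        assert np.allclose(reconstruct_cp(M, C, D), loop_reconstruct(M, C, D),
                           atol=1e-12)


class TestRowWeight:
    def test_printed_convention_is_half_column_norm(self):
        W = row_weight(np.array([[3.0], [4.0]]))
        assert W[0, 0] == pytest.approx(2.5)

    def test_zero_matrix(self):
        assert not row_weight(np.zeros((3, 2))).any()

    def test_diagonal_only(self):
        rng = np.random.default_rng(7)
        W = row_weight(rng.uniform(size=(5, 3)))
        assert np.array_equal(W, np.diag(np.diag(W)))

    def test_standard_convention_inverse_norm(self):
        W = row_weight(np.array([[3.0], [4.0]]), convention="standard")
        assert W[0, 0] == pytest.approx(1.0 / 10.0, rel=1e-9)


class TestBlockUpdates:
    def test_z_reduces_to_consensus_when_alpha_zero(self):
        rng = np.random.default_rng(8)
        st, Sm, Sd = make_state(rng)
        hp = MCTDHyperparams(r=2, alpha=0.0)
        Z = block_update("Z", st, hp, Sm, Sd)
        assert np.allclose(Z, st.factors.M + st.Y2 / st.rho2, atol=1e-12)

    def test_f_reduces_to_consensus_when_beta_zero(self):
        rng = np.random.default_rng(9)
        st, Sm, Sd = make_state(rng)
        hp = MCTDHyperparams(r=2, beta=0.0)
        F = block_update("F", st, hp, Sm, Sd)
        assert np.allclose(F, st.factors.D + st.Y3 / st.rho3, atol=1e-12)

    @pytest.mark.parametrize("block", ["M", "C", "H", "Z", "D", "P", "F"])
    def test_update_is_stationary_point(self, block):
        rng = np.random.default_rng(10)
        st, Sm, Sd = make_state(rng)
        hp = MCTDHyperparams(r=2)
        new = block_update(block, st, hp, Sm, Sd)
        g = numeric_block_gradient(block, new, st, hp, Sm, Sd)
        scale = max(1.0, np.abs(new).max())
        assert np.abs(g).max() <= 1e-6 * scale

    def test_update_beats_random_perturbations(self):
        rng = np.random.default_rng(11)
        st, Sm, Sd = make_state(rng)
        hp = MCTDHyperparams(r=2)
        for block in ("M", "D", "C"):
            Wm = row_weight(st.factors.M)
            Wd = row_weight(st.factors.D)
            new = block_update(block, st, hp, Sm, Sd)
            base = augmented_lagrangian(st, hp, Sm, Sd, W_m=Wm, W_d=Wd,
                                        overrides={block: new})
            for _ in range(10):
                pert = new + 1e-2 * rng.standard_normal(new.shape)
                assert augmented_lagrangian(
                    st, hp, Sm, Sd, W_m=Wm, W_d=Wd,
                    overrides={block: pert}) >= base


class TestMultipliers:
    def test_penalties_scale_by_eps(self):
        rng = np.random.default_rng(12)
        st, _, _ = make_state(rng)
        hp = MCTDHyperparams(r=2, eps_scale=1.15)
        st = update_multipliers(st, hp)
        for p in (st.rho1, st.rho2, st.rho3, st.theta1, st.theta2):
            assert p == pytest.approx(1.15)

    def test_zero_residual_leaves_multiplier(self):
        rng = np.random.default_rng(13)
        st, _, _ = make_state(rng)
        st.factors.C = st.factors.M.copy()
        Y1 = st.Y1.copy()
        st = update_multipliers(st, MCTDHyperparams(r=2))
        assert np.array_equal(st.Y1, Y1)

    def test_scalar_arithmetic_case(self):
        rng = np.random.default_rng(14)
        st, _, _ = make_state(rng, nA=1, nB=1, r=1, penalties=2.0)
        st.factors.M = np.array([[1.0]])
        st.factors.C = np.array([[0.0]])
        st.Y1 = np.array([[0.0]])
        st = update_multipliers(st, MCTDHyperparams(r=1))
        assert st.Y1[0, 0] == 2.0


class TestProjectionCG:
    def test_zero_target_gives_zero(self):
        rng = np.random.default_rng(15)
        M = rng.uniform(size=(4, 2))
        A = cg_solve_projection(np.zeros((4, 4)), M, mu=1.0, lam=0.1)
        assert not A.any()

    def test_matches_kronecker_direct_solve(self):
        rng = np.random.default_rng(16)
        for _ in range(5):
            M = rng.uniform(size=(4, 2))
            S = random_similarity(rng, 4).values
            mu, lam = 1.0, 0.3
            A = cg_solve_projection(S, M, mu, lam, iters=100, tol=1e-14)
            MtM = M.T @ M
            lhs = mu * np.kron(MtM, MtM) + lam * np.eye(4)
            rhs = mu * (M.T @ S @ M).ravel()
            A_direct = np.linalg.solve(lhs, rhs).reshape(2, 2)
            assert np.allclose(A, A_direct, rtol=1e-6, atol=1e-10)

    def test_ridge_limit_shrinks_to_zero(self):
        rng = np.random.default_rng(17)
        M = rng.uniform(size=(4, 2))
        S = random_similarity(rng, 4)
        A = cg_solve_projection(S, M, mu=1.0, lam=1e9)
        assert np.linalg.norm(A) < 1e-6

    def test_result_is_symmetric_for_symmetric_target(self):
        rng = np.random.default_rng(18)
        M = rng.uniform(size=(5, 2))
        A = cg_solve_projection(random_similarity(rng, 5), M, 0.5, 0.1)
        assert np.allclose(A, A.T, atol=1e-10)


class TestImpute:
    def test_fully_observed_returns_input(self):
        rng = np.random.default_rng(19)
        X = rng.uniform(size=(2, 2, 2))
        X = 0.5 * (X + X.transpose(1, 0, 2))
        fac = FactorSet(M=rng.uniform(size=(2, 2)), C=rng.uniform(size=(2, 2)),
                        D=rng.uniform(size=(2, 2)), A_m=np.zeros((2, 2)),
                        A_d=np.zeros((2, 2)))
        out = impute((X, np.ones_like(X, dtype=bool)), fac)
        assert np.array_equal(out, X)

    def test_fully_unobserved_returns_model(self):
        rng = np.random.default_rng(20)
        fac = FactorSet(M=rng.uniform(size=(2, 2)), C=rng.uniform(size=(2, 2)),
                        D=rng.uniform(size=(2, 2)), A_m=np.zeros((2, 2)),
                        A_d=np.zeros((2, 2)))
        X = np.zeros((2, 2, 2))
        out = impute((X, np.zeros_like(X, dtype=bool)), fac)
        assert np.allclose(out, reconstruct_cp(fac.M, fac.C, fac.D))

    def test_mixed_mask_matches_per_cell_branch(self):
        rng = np.random.default_rng(21)
        X = rng.uniform(size=(2, 2, 2))
        O = rng.uniform(size=(2, 2, 2)) < 0.5
        fac = FactorSet(M=rng.uniform(size=(2, 2)), C=rng.uniform(size=(2, 2)),
                        D=rng.uniform(size=(2, 2)), A_m=np.zeros((2, 2)),
                        A_d=np.zeros((2, 2)))
        out = impute((X, O), fac)
        model = reconstruct_cp(fac.M, fac.C, fac.D)
        for idx in np.ndindex(2, 2, 2):
            assert out[idx] == (X[idx] if O[idx] else model[idx])


class TestFit:
    def test_deterministic_under_seed(self, planted_default):
        from convntc import build_tensor
        ds, Sm, Sd, _ = planted_default
        X = build_tensor(ds)
        hp = MCTDHyperparams(r=2, max_iters=10, seed=123)
        fa, _ = mctd_fit(X, Sm, Sd, hp)
        fb, _ = mctd_fit(X, Sm, Sd, hp)
        assert np.array_equal(fa.M, fb.M)
        assert np.array_equal(fa.D, fb.D)
        assert np.array_equal(fa.A_m, fb.A_m)

    def test_planted_recovery_and_consensus(self, noiseless_rank2):
        # noiseless recovery uses no constraint bias and gentle initial
        # penalties so the data term dominates the early sweeps
        X, Sm, Sd, _ = noiseless_rank2
        hp = MCTDHyperparams(r=2, mu=0.0, eta=0.0, alpha=0.0, beta=0.0,
                             lam=1e-9, rho1=0.01, rho2=0.01, rho3=0.01,
                             theta1=0.01, theta2=0.01, max_iters=200,
                             tol=1e-12, seed=5)
        _, diag = mctd_fit(X, Sm, Sd, hp)
        assert diag["obs_rel_error"][-1] < 1e-2
        for name, series in diag["residuals"].items():
            assert series[-1] < series[4], name

    def test_consensus_ratio_shrinks_on_planted_instance(self, noiseless_rank2):
        X, Sm, Sd, _ = noiseless_rank2
        hp = MCTDHyperparams(r=2, max_iters=120, tol=1e-12, seed=5)
        factors, diag = mctd_fit(X, Sm, Sd, hp)
        ratio = diag["residuals"]["M-C"][-1] / np.linalg.norm(factors.M)
        assert ratio < 1e-2
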