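import numpy as np
import pytest

from multifactv.factorization import (
    FactorSet,
    Hyperparameters,
    fit,
    fit_restarts,
    objective,
    solve_condition_factor,
    solve_gene_factor,
    solve_time_factor_admm,
)
from multifactv.tensor_core import difference_matrix, khatri_rao, unfold

from conftest import cp_tensor


def brute_force_objective(a, U, V, W, alpha):
    """Triple-loop evaluation of the penalized objective."""
    n1, n2, n3 = a.shape
    K = U.shape[1]
    total = 0.0
    for r in range(n1):
        for s in range(n2):
            for t in range(n3):
                approx = sum(U[r, k] * V[s, k] * W[t, k] for k in range(K))
                total += (a[r, s, t] - approx) ** 2
    for k in range(K):
        for t in range(n3 - 1):
            total += alpha * abs(W[t, k] - W[t + 1, k])
    return total


class TestObjective:
    def test_matches_triple_loop(self):
        a = np.arange(12, dtype=float).reshape(2, 2, 3)
        U = np.array([[1.0], [2.0]])
        V = np.array([[1.0], [-1.0]])
        W = np.array([[0.5], [0.3], [0.2]])
        got = objective(a, FactorSet(U, V, W), alpha=3.0)
        assert got == pytest.approx(brute_force_objective(a, U, V, W, 3.0), rel=1e-12)

    def test_zero_on_exact_fit_with_constant_w(self, rng):
        U, V = rng.normal(size=(3, 2)), rng.normal(size=(4, 2))
        W = np.full((5, 2), 0.2)  # constant simplex columns: zero TV
        a = cp_tensor(U, V, W)
        assert objective(a, FactorSet(U, V, W), alpha=7.0) == pytest.approx(0.0, abs=1e-12)

    def test_alpha_zero_is_residual_only(self, rng):
        U, V, W = (rng.normal(size=(n, 2)) for n in (3, 4, 5))
        a = rng.normal(size=(3, 4, 5))
        resid = np.sum((a - cp_tensor(U, V, W)) ** 2)
        assert objective(a, FactorSet(U, V, W), 0.0) == pytest.approx(resid)

    def test_dimension_mismatch(self, rng):
        U, V, W = (rng.normal(size=(n, 2)) for n in (3, 4, 5))
        with pytest.raises(ValueError, match="dims"):
            objective(np.zeros((3, 4, 6)), FactorSet(U, V, W), 1.0)


class TestClosedFormUpdates:
    def test_rank1_recovery_residual_zero(self, rng):
        u, v, w = rng.normal(size=(4, 1)), rng.normal(size=(3, 1)), rng.normal(size=(5, 1))
        a = cp_tensor(u, v, w)
        U = solve_gene_factor(unfold(a, 1), v, w)
        resid = unfold(a, 1) - U @ khatri_rao(w, v).T
        assert np.abs(resid).max() < 1e-10

    def test_orthonormal_rows_case(self):
        # V, W basis columns make F's rows orthonormal, so U = A1 F^T
        V = np.eye(2)
        W = np.eye(2)
        a = np.arange(8, dtype=float).reshape(2, 2, 2)
        a1 = unfold(a, 1)
        f = khatri_rao(W, V)
        np.testing.assert_allclose(solve_gene_factor(a1, V, W), a1 @ f)

    @pytest.mark.parametrize("which", ["gene", "condition"])
    def test_beats_random_perturbations(self, rng, which):
        a = rng.normal(size=(3, 2, 2))
        W = rng.normal(size=(2, 2))
        if which == "gene":
            V = rng.normal(size=(2, 2))
            a_unf = unfold(a, 1)
            F = khatri_rao(W, V).T
            X = solve_gene_factor(a_unf, V, W)
        else:
            U = rng.normal(size=(3, 2))
            a_unf = unfold(a, 2)
            F = khatri_rao(W, U).T
            X = solve_condition_factor(a_unf, U, W)
        best = np.sum((a_unf - X @ F) ** 2)
        for _ in range(1000):
            cand = X + rng.normal(size=X.shape) * rng.uniform(0.001, 1.0)
            assert np.sum((a_unf - cand @ F) ** 2) >= best - 1e-12

    def test_subproblem_symmetry(self, rng):
        # symmetric tensor with U == V: both updates return the same matrix
        U0 = rng.normal(size=(3, 2))
        W0 = np.abs(rng.normal(size=(4, 2)))
        W0 /= W0.sum(axis=0)
        a = cp_tensor(U0, U0, W0)
        got_u = solve_gene_factor(unfold(a, 1), U0, W0)
        got_v = solve_condition_factor(unfold(a, 2), U0, W0)
        np.testing.assert_allclose(got_u, got_v, atol=1e-10)


class TestTimeFactorADMM:
    def test_alpha_zero_matches_least_squares(self, rng):
        U, V = rng.normal(size=(3, 2)), rng.normal(size=(4, 2))
        a = rng.normal(size=(3, 4, 5))
        a3 = unfold(a, 3)
        f = khatri_rao(V, U)
        w_ls = np.linalg.solve(f.T @ f, f.T @ a3.T).T
        W, _, _, _ = solve_time_factor_admm(
            a3, U, V, alpha=0.0, rho=1.0, inner_tol=1e-12, inner_max_iter=500,
            project=False,
        )
        np.testing.assert_allclose(W, w_ls, atol=1e-6)

    def test_matches_simplex_grid_search(self):
        """K=1, n3=4 instance: projected ADMM result is at least as good as a
        dense 0.01-resolution grid search over the simplex (within 1e-3)."""
        u = np.array([[2.0], [2.0]])
        v = np.array([[1.0], [2.0]])
        f = khatri_rao(v, u).ravel()
        a3 = np.outer([0.5, 0.5, 0.0, 0.0], f)  # small integer entries
        assert np.array_equal(a3, np.round(a3))
        alpha, rho = 10.0, 1.0
        B = difference_matrix(4)
        W, _, _, _ = solve_time_factor_admm(
            a3, u, v, alpha, rho, inner_tol=1e-10, inner_max_iter=5000
        )
        w = W.ravel()
        got = np.sum((a3 - np.outer(w, f)) ** 2) + alpha * np.abs(B @ w).sum()

        # enumerate the 3-simplex at resolution 0.01
        r = 100
        pts = [
            (i, j, k, r - i - j - k)
            for i in range(r + 1)
            for j in range(r + 1 - i)
            for k in range(r + 1 - i - j)
        ]
        G = np.asarray(pts, float) / r
        # ||a3 - w f^T||^2 expanded; exact for every grid point
        obj = (
            np.sum(a3 * a3)
            - 2.0 * G @ (a3 @ f)
            + np.sum(G * G, axis=1) * (f @ f)
            + alpha * np.abs(G @ B.T).sum(axis=1)
        )
        assert got <= obj.min() + 1e-3

    def test_tv_never_increases_variation(self, rng):
        # data with a constant true time profile
        U, V = rng.normal(size=(4, 1)), rng.normal(size=(3, 1))
        a = cp_tensor(U, V, np.full((6, 1), 1 / 6)) + 0.01 * rng.normal(size=(4, 3, 6))
        a3 = unfold(a, 3)
        B = difference_matrix(6)
        W0, _, _, _ = solve_time_factor_admm(a3, U, V, alpha=0.0, rho=1.0)
        W1, _, _, _ = solve_time_factor_admm(a3, U, V, alpha=5.0, rho=1.0)
        assert np.abs(B @ W1).sum() <= np.abs(B @ W0).sum() + 1e-10

    def test_rejects_nonpositive_rho(self, rng):
        with pytest.raises(ValueError, match="rho"):
            solve_time_factor_admm(np.zeros((3, 4)), np.ones((2, 1)), np.ones((2, 1)),
                                   1.0, 0.0)


class TestFit:
    def test_noiseless_recovery_small_residual(self):
        """Constant-signal planted modules are exactly rank-3: the converged
        reconstruction error is below 1% of the tensor energy for 5 seeds."""
        from multifactv.synthetic_data import generate_planted_tensor

        for seed in range(5):
            tensor, _ = generate_planted_tensor(
                60, 60, 20, K=3, genes_per_module=10, conditions_per_module=10,
                interval_length=5, noise_density=0.0, seed=seed,
                signal_low=0.8, signal_high=0.8,
            )
            res = fit(tensor, Hyperparameters(K=3, alpha=1.0, seed=seed))
            energy = np.sum(tensor.values**2)
            resid = objective(tensor, res.factors, alpha=0.0)
            assert resid <= 0.01 * energy

    def test_objective_trace_descends(self, small_planted):
        tensor, _ = small_planted
        res = fit(tensor, Hyperparameters(K=3, alpha=1.0, seed=0))
        assert np.all(np.isfinite(res.objective_trace))
        assert res.objective_trace[-1] < res.objective_trace[0]

    def test_w_constraints_every_outer_iteration(self, small_planted):
        tensor, _ = small_planted
        snapshots = []
        fit(tensor, Hyperparameters(K=3, alpha=1.0, seed=1),
            callback=lambda t, fac: snapshots.append(fac.W.copy()))
        assert snapshots
        for W in snapshots:
            assert W.min() >= -1e-10
            np.testing.assert_allclose(W.sum(axis=0), np.ones(3), atol=1e-10)

    def test_residual_nonincreasing_over_u_and_v_updates(self, small_planted):
        tensor, _ = small_planted
        res = fit(tensor, Hyperparameters(K=3, alpha=1.0, seed=2), track_residuals=True)
        r = np.array(res.residual_trace).reshape(-1, 3)  # after U, after V, after W
        # within an iteration the exact LS updates cannot increase the residual
        assert np.all(r[:, 1] <= r[:, 0] * (1 + 1e-9) + 1e-9)
        # the U update improves on the previous iteration's end state
        assert np.all(r[1:, 0] <= r[:-1, 2] * (1 + 1e-9) + 1e-9)

    def test_large_alpha_flattens_time_profiles(self, small_planted):
        # rho is scaled with alpha so the ADMM dual reaches the TV-dominated
        # fixed point within the inner iteration budget
        tensor, _ = small_planted
        res = fit(tensor, Hyperparameters(K=3, alpha=1e4, rho=1e4, seed=3))
        W = res.factors.W
        assert np.all(W.max(axis=0) - W.min(axis=0) <= 1e-3)

    def test_fixed_seed_is_bitwise_deterministic(self, small_planted):
        tensor, _ = small_planted
        hp = Hyperparameters(K=3, alpha=1.0, seed=42)
        r1, r2 = fit(tensor, hp), fit(tensor, hp)
        assert r1.objective_trace == r2.objective_trace
        np.testing.assert_array_equal(r1.factors.U, r2.factors.U)
        np.testing.assert_array_equal(r1.factors.V, r2.factors.V)
        np.testing.assert_array_equal(r1.factors.W, r2.factors.W)

    def test_beats_random_feasible_triplets(self, rng):
        a = rng.normal(size=(2, 2, 3))
        alpha = 1.0
        res = fit_restarts(a, Hyperparameters(K=1, alpha=alpha, seed=0), n_restarts=3)
        best_random = np.inf
        for _ in range(10_000):
            U = rng.normal(size=(2, 1))
            V = rng.normal(size=(2, 1))
            W = rng.uniform(size=(3, 1))
            W /= W.sum(axis=0)
            best_random = min(best_random, objective(a, FactorSet(U, V, W), alpha))
        assert res.objective <= best_random + 1e-9

    def test_nonconvergence_reported(self, small_planted):
        tensor, _ = small_planted
        res = fit(tensor, Hyperparameters(K=3, alpha=1.0, seed=0, outer_max_iter=1))
        assert res.converged is False
        assert res.n_outer_iterations == 1

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            Hyperparameters(K=0).validate()
        with pytest.raises(ValueError):
            Hyperparameters(K=2, tau1=1.5).validate()
        with pytest.raises(ValueError):
            Hyperparameters(K=2, rho=-1.0).validate()
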