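"""The sparse canonical solver: block updates, objective, convergence, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from osscca.data import impute_and_standardize
from osscca.solver import (
    OsSccaConfig,
    fit_oscca,
    oracle_search,
    penalized_objective,
    soft_threshold,
    update_loading,
)

from conftest import standardized_instance


def pmd_sparse_cca_reference(X, Y, lambda_u, lambda_v, max_iter=100, tol=1e-6):
    """Independent two-way sparse-CCA reference: rank-1 penalized matrix
    decomposition of XᵀY, written as explicit loops (soft-threshold each
    block gradient, renormalize), same deterministic SVD init."""
    C = X.T @ Y
    _, _, vt = np.linalg.svd(C, full_matrices=False)
    v = vt[0].copy()
    j = max(range(v.size), key=lambda i: abs(v[i]))
    if v[j] < 0:
        v = -v
    u = np.zeros(C.shape[0])
    for _ in range(max_iter):
        gu = C @ v
        u_new = np.array(
            [np.sign(g) * max(abs(g) - lambda_u, 0.0) for g in gu]
        )
        nu = np.sqrt((u_new**2).sum())
        if nu > 0:
            u_new = u_new / nu
        gv = C.T @ u_new
        v_new = np.array(
            [np.sign(g) * max(abs(g) - lambda_v, 0.0) for g in gv]
        )
        nv = np.sqrt((v_new**2).sum())
        if nv > 0:
            v_new = v_new / nv
        delta = max(np.abs(u_new - u).max(), np.abs(v_new - v).max())
        u, v = u_new, v_new
        if delta < tol:
            break
    objective = -u @ C @ v + lambda_u * np.abs(u).sum() + lambda_v * np.abs(v).sum()
    return u, v, objective


class TestSoftThreshold:
    def test_definition(self):
        np.testing.assert_allclose(
            soft_threshold(np.array([3.0, -1.0, 0.5]), 1.0), [2.0, 0.0, 0.0]
        )

    def test_identity_at_zero(self, rng):
        a = rng.standard_normal(10)
        np.testing.assert_array_equal(soft_threshold(a, 0.0), a)

    def test_total_shrinkage(self, rng):
        a = rng.standard_normal(10)
        assert np.all(soft_threshold(a, np.abs(a).max()) == 0.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)

    @given(
        arrays(float, 6, elements=st.floats(-10, 10)),
        st.floats(0, 5),
    )
    @settings(deadline=None)
    def test_shrinks_toward_zero(self, a, t):
        out = soft_threshold(a, t)
        assert np.all(np.abs(out) <= np.maximum(np.abs(a) - t, 0.0) + 1e-12)
        assert np.all(np.sign(out) * np.sign(a) >= 0)


class TestPenalizedObjective:
    def test_zero_loadings_give_zero(self, rng):
        X = rng.standard_normal((5, 3))
        Y = rng.standard_normal((5, 2))
        Z = rng.standard_normal(5)
        assert penalized_objective(np.zeros(3), np.zeros(2), X, Y, Z, 1.0, 0.3, 0.4) == 0.0

    def test_hand_arithmetic(self):
        X = np.array([[1.0], [-1.0]])
        Y = np.array([[1.0], [-1.0]])
        Z = np.array([1.0, -1.0])
        val = penalized_objective(np.array([1.0]), np.array([1.0]), X, Y, Z, 1.0, 0.0, 0.0)
        assert val == pytest.approx(-6.0)

    def test_matches_independent_termwise_computation(self, rng):
        for _ in range(10):
            n, p, q = 8, 3, 4
            X = rng.standard_normal((n, p))
            Y = rng.standard_normal((n, q))
            Z = rng.standard_normal(n)
            u = rng.standard_normal(p)
            v = rng.standard_normal(q)
            w, lu, lv = rng.uniform(0.1, 2, 3)
            # independent arithmetic: explicit double sums
            bilinear = sum(
                u[a] * sum(X[i, a] * Y[i, b] for i in range(n)) * v[b]
                for a in range(p)
                for b in range(q)
            )
            yz = sum(v[b] * sum(Y[i, b] * Z[i] for i in range(n)) for b in range(q))
            xz = sum(u[a] * sum(X[i, a] * Z[i] for i in range(n)) for a in range(p))
            expected = (
                -bilinear - w * yz - w * xz
                + lu * sum(abs(x) for x in u)
                + lv * sum(abs(x) for x in v)
            )
            assert penalized_objective(u, v, X, Y, Z, w, lu, lv) == pytest.approx(expected)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            penalized_objective(
                np.ones(2), np.ones(2), rng.standard_normal((4, 3)),
                rng.standard_normal((4, 2)), np.zeros(4), 1.0, 0, 0,
            )


class TestUpdateLoading:
    def test_no_shrinkage_normalizes(self, rng):
        g = rng.standard_normal(5)
        np.testing.assert_allclose(update_loading(g, 0.0), g / np.linalg.norm(g))

    def test_full_shrinkage_gives_zero(self, rng):
        g = rng.standard_normal(5)
        assert np.all(update_loading(g, np.abs(g).max()) == 0.0)

    def test_single_survivor(self):
        np.testing.assert_allclose(update_loading(np.array([3.0, 1.0]), 1.0), [1.0, 0.0])


class TestFitOscca:
    def test_one_dimensional_aligned(self):
        z = np.array([1.0, -1.0, 0.5, -0.5])
        Xs, _ = impute_and_standardize(z.reshape(-1, 1))
        sol = fit_oscca(Xs, Xs.copy(), Xs[:, 0], OsSccaConfig())
        np.testing.assert_allclose(sol.u, [1.0], atol=1e-9)
        np.testing.assert_allclose(sol.v, [1.0], atol=1e-9)

    def test_penalty_dominates(self):
        X, Y, z = standardized_instance(0)
        big = 10.0 * max(np.abs(X.T @ Y).sum(), np.abs(X.T @ z).max(), np.abs(Y.T @ z).max())
        sol = fit_oscca(X, Y, z, OsSccaConfig(lambda_u=big, lambda_v=big))
        assert np.all(sol.u == 0.0) and np.all(sol.v == 0.0)
        assert sol.objective == 0.0

    def test_planted_support_recovered(self):
        rng = np.random.default_rng(42)
        n = 30
        latent = rng.standard_normal(n)
        X = rng.standard_normal((n, 3)) * 0.1
        Y = rng.standard_normal((n, 3)) * 0.1
        X[:, 0] += latent
        Y[:, 0] += latent
        z_raw = latent + 0.1 * rng.standard_normal(n)
        Xs, _ = impute_and_standardize(X)
        Ys, _ = impute_and_standardize(Y)
        Zs, _ = impute_and_standardize(z_raw)
        gu = np.abs(Xs.T @ Ys @ np.array([1.0, 0, 0]) + Xs.T @ Zs[:, 0]).max()
        sol = fit_oscca(Xs, Ys, Zs[:, 0], OsSccaConfig(lambda_u=0.5 * gu, lambda_v=0.5 * gu))
        assert set(np.flatnonzero(sol.u)) == {0}
        assert set(np.flatnonzero(sol.v)) == {0}

    def test_non_finite_input_rejected(self):
        X, Y, z = standardized_instance(1)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_oscca(X, Y, z, OsSccaConfig())

    def test_trajectory_non_increasing(self):
        for seed in range(20):
            X, Y, z = standardized_instance(seed, n=25, p=6, q=5, signal=0.3)
            lam = np.random.default_rng(seed).uniform(0, 3, 2)
            sol = fit_oscca(X, Y, z, OsSccaConfig(lambda_u=lam[0], lambda_v=lam[1]))
            diffs = np.diff(sol.objective_trajectory)
            assert np.all(diffs <= 1e-9)

    def test_column_permutation_equivariance(self):
        X, Y, z = standardized_instance(3, n=20, p=5, q=4, signal=0.5)
        cfg = OsSccaConfig(lambda_u=0.8, lambda_v=0.8)
        sol = fit_oscca(X, Y, z, cfg)
        perm = np.array([3, 0, 4, 1, 2])
        sol_p = fit_oscca(X[:, perm], Y, z, cfg)
        np.testing.assert_allclose(sol_p.u, sol.u[perm], atol=1e-8)
        np.testing.assert_allclose(sol_p.v, sol.v, atol=1e-8)

    def test_sign_convention_two_way(self):
        # at w=0 the objective is invariant under a joint sign flip; the
        # convention corr(Xu, Z) >= 0 makes the output unique
        for seed in range(5):
            X, Y, z = standardized_instance(seed, signal=0.4)
            sol = fit_oscca(X, Y, z, OsSccaConfig(w=0.0, lambda_u=0.3, lambda_v=0.3))
            if np.any(sol.u):
                xu = X @ sol.u
                if np.ptp(xu) > 0:
                    assert xu @ z >= -1e-9
                flipped = penalized_objective(-sol.u, -sol.v, X, Y, z, 0.0, 0.3, 0.3)
                assert flipped == pytest.approx(sol.objective, abs=1e-9)

    def test_sparsity_monotone_in_lambda_u(self):
        X, Y, z = standardized_instance(9, n=40, p=8, q=6, signal=0.4)
        gu, _ = np.abs(X.T @ Y).max(), None
        sizes = []
        for lam in np.linspace(0.0, 2 * np.abs(X.T @ z).max() + gu, 12):
            sol = fit_oscca(X, Y, z, OsSccaConfig(lambda_u=lam, lambda_v=0.1))
            sizes.append(int(np.count_nonzero(sol.u)))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_deterministic(self):
        X, Y, z = standardized_instance(11, signal=0.3)
        cfg = OsSccaConfig(lambda_u=0.5, lambda_v=0.5, init="random", seed=7)
        s1 = fit_oscca(X, Y, z, cfg)
        s2 = fit_oscca(X, Y, z, cfg)
        np.testing.assert_array_equal(s1.u, s2.u)
        np.testing.assert_array_equal(s1.v, s2.v)


class TestTwoWayReduction:
    def test_matches_pmd_reference(self):
        for seed in range(10):
            X, Y, z = standardized_instance(seed, n=25, p=5, q=4, signal=0.4)
            lu, lv = np.random.default_rng(seed).uniform(0.1, 1.5, 2)
            sol = fit_oscca(X, Y, z, OsSccaConfig(lambda_u=lu, lambda_v=lv, w=0.0))
            u_ref, v_ref, obj_ref = pmd_sparse_cca_reference(X, Y, lu, lv)
            # align the reference with the solver's documented sign convention
            xu = X @ u_ref
            if np.ptp(xu) > 0 and xu @ z < 0:
                u_ref, v_ref = -u_ref, -v_ref
            np.testing.assert_allclose(sol.u, u_ref, atol=1e-6)
            np.testing.assert_allclose(sol.v, v_ref, atol=1e-6)
            assert sol.objective == pytest.approx(obj_ref, abs=1e-6)


class TestOracleSearch:
    def test_zero_signal_large_penalty(self):
        X, Y, z = standardized_instance(0)
        cfg = OsSccaConfig(lambda_u=1e3, lambda_v=1e3)
        assert oracle_search(X, Y, z, cfg, n_restarts=200, seed=0) == 0.0

    def test_minimum_property(self, rng):
        X, Y, z = standardized_instance(5, n=15, p=3, q=3)
        cfg = OsSccaConfig(lambda_u=0.4, lambda_v=0.4)
        best = oracle_search(X, Y, z, cfg, n_restarts=2000, seed=1)
        for _ in range(50):
            u = rng.standard_normal(3)
            u /= max(np.linalg.norm(u), 1.0)
            v = rng.standard_normal(3)
            v /= max(np.linalg.norm(v), 1.0)
            assert best <= penalized_objective(u, v, X, Y, z, 1.0, 0.4, 0.4) + 1e-9

    def test_solver_attains_oracle_small_instances(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, p, q = rng.integers(8, 21), rng.integers(1, 5), rng.integers(1, 5)
            X, Y, z = standardized_instance(seed + 100, n=int(n), p=int(p), q=int(q),
                                            signal=0.5)
            cfg = OsSccaConfig(lambda_u=rng.uniform(0, 2), lambda_v=rng.uniform(0, 2))
            sol = fit_oscca(X, Y, z, cfg)
            best = oracle_search(X, Y, z, cfg, n_restarts=4000, seed=seed)
            assert sol.objective == pytest.approx(best, abs=1e-3)


def test_solution_json_round_trip(tmp_path):
    import json

    X, Y, z = standardized_instance(2, signal=0.4)
    sol = fit_oscca(X, Y, z, OsSccaConfig(lambda_u=0.3, lambda_v=0.3),
                    imaging_names=[f"f{i}" for i in range(4)],
                    variant_names=[f"v{i}" for i in range(3)])
    text = sol.to_json(tmp_path / "sol.json")
    payload = json.loads(text)
    assert payload["converged"] is True
    assert list(payload["u"]) == [f"f{i}" for i in range(4)]
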