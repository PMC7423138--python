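"""Sparse CCA solver: exact limits, oracles, invariances, convergence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuroscca import (
    ConfigError,
    DataError,
    PenaltyPair,
    canonical_correlation,
    generate_coupled_dataset,
    scca_fit,
    standardize_columns,
)
from oracles import scca_grid_max


def _standardize(A):
    return (A - A.mean(axis=0)) / A.std(axis=0, ddof=1)


class TestStandardize:
    def test_zero_mean_unit_variance(self):
        M = np.array([[1.0, 5.0], [2.0, 9.0], [3.0, 4.0]])
        Z, scaler = standardize_columns(M)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_idempotent_on_standardized_input(self, rng):
        M = _standardize(rng.standard_normal((40, 5)))
        Z, _ = standardize_columns(M)
        np.testing.assert_allclose(Z, M, atol=1e-12)

    def test_rare_binary_column_centers_exactly(self):
        col = np.zeros(50)
        col[:5] = 1.0
        Z, _ = standardize_columns(col[:, None])
        assert abs(Z.mean()) < 1e-12

    def test_constant_column_dropped_or_rejected(self):
        M = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(DataError):
            standardize_columns(M)
        with pytest.warns(UserWarning):
            Z, scaler = standardize_columns(M, drop_constant=True)
        assert Z.shape[1] == 1 and scaler.n_dropped == 1
        np.testing.assert_array_equal(scaler.expand(np.array([0.7])), [0.7, 0.0])


class TestPenaltyPair:
    def test_budgets_below_one_rejected(self):
        with pytest.raises(ConfigError):
            PenaltyPair(0.5, 2.0)


class TestSccaFit:
    def test_noiseless_rank_one_recovered_exactly(self, rng):
        n, p, q = 50, 6, 4
        a = rng.standard_normal(p)
        b = rng.standard_normal(q)
        z = rng.standard_normal(n)
        X = _standardize(np.outer(z, a))
        Y = _standardize(np.outer(z, b))
        sol = scca_fit(X, Y, PenaltyPair(np.sqrt(p), np.sqrt(q)))
        assert sol.rho == pytest.approx(1.0, abs=1e-6)
        # columns of a rank-1 standardized matrix are +-z, so the recovered
        # combination must align with the sign pattern of a (resp. b)
        ua = sol.u @ (np.sign(a) / np.sqrt(p))
        vb = sol.v @ (np.sign(b) / np.sqrt(q))
        assert abs(ua) >= 1 - 1e-6 and abs(vb) >= 1 - 1e-6

    def test_budget_one_forces_single_feature(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = _standardize(r.standard_normal((20, 6)))
            Y = _standardize(r.standard_normal((20, 4)))
            sol = scca_fit(X, Y, PenaltyPair(1.0, np.sqrt(4)))
            assert np.count_nonzero(sol.u) == 1
            j = int(np.flatnonzero(sol.u)[0])
            assert j == int(np.argmax(np.abs(X.T @ Y @ sol.v)))

    def test_unpenalized_limit_matches_svd_pair(self, rng):
        X = _standardize(rng.standard_normal((30, 8)))
        Y = _standardize(rng.standard_normal((30, 5)))
        sol = scca_fit(X, Y, PenaltyPair(np.sqrt(8), np.sqrt(5)))
        U, _, Vt = np.linalg.svd(X.T @ Y)
        assert abs(sol.u @ U[:, 0]) >= 1 - 1e-6
        assert abs(sol.v @ Vt[0]) >= 1 - 1e-6

    def test_objective_matches_grid_search_oracle(self, rng):
        """Dense grid search over the constraint set on tiny problems."""
        for seed in range(4):
            r = np.random.default_rng(100 + seed)
            X = _standardize(r.standard_normal((5, 3)))
            Y = _standardize(r.standard_normal((5, 2)))
            pen = PenaltyPair(1.2, 1.2)
            sol = scca_fit(X, Y, pen)
            fitted = float(sol.u @ X.T @ Y @ sol.v)
            oracle = scca_grid_max(X.T @ Y, pen.c1, pen.c2)
            assert fitted == pytest.approx(oracle, abs=1e-3)

    def test_objective_trace_is_monotone(self, standardized_planted):
        Xs, Ys, _ = standardized_planted
        sol = scca_fit(Xs, Ys, PenaltyPair(2.5, 2.0))
        diffs = np.diff(sol.objective_trace)
        assert np.all(diffs >= -1e-10)

    def test_feature_permutation_equivariance(self, standardized_planted):
        Xs, Ys, _ = standardized_planted
        pen = PenaltyPair(2.0, 1.8)
        base = scca_fit(Xs, Ys, pen)
        rng = np.random.default_rng(3)
        perm_x = rng.permutation(Xs.shape[1])
        perm_y = rng.permutation(Ys.shape[1])
        permuted = scca_fit(Xs[:, perm_x], Ys[:, perm_y], pen)
        np.testing.assert_allclose(permuted.u, base.u[perm_x], atol=1e-8)
        np.testing.assert_allclose(permuted.v, base.v[perm_y], atol=1e-8)

    def test_objective_nondecreasing_in_budget(self, standardized_planted):
        """Feasible sets nest as c1 grows, so the optimum cannot decrease."""
        Xs, Ys, _ = standardized_planted
        M = Xs.T @ Ys
        objectives = []
        for c1 in np.linspace(1.0, np.sqrt(Xs.shape[1]), 6):
            sol = scca_fit(Xs, Ys, PenaltyPair(float(c1), 2.0))
            objectives.append(float(sol.u @ M @ sol.v))
        assert np.all(np.diff(objectives) >= -1e-8)

    def test_l1_and_l2_constraints_hold(self, standardized_planted):
        Xs, Ys, _ = standardized_planted
        pen = PenaltyPair(1.7, 1.4)
        sol = scca_fit(Xs, Ys, pen)
        assert np.linalg.norm(sol.u) <= 1 + 1e-8
        assert np.linalg.norm(sol.v) <= 1 + 1e-8
        assert np.abs(sol.u).sum() <= pen.c1 + 1e-8
        assert np.abs(sol.v).sum() <= pen.c2 + 1e-8

    def test_shape_mismatch_and_nan_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(DataError):
            scca_fit(X, np.zeros((8, 2)), PenaltyPair(1.5, 1.2))
        Y = np.zeros((10, 2))
        Y[0, 0] = np.nan
        with pytest.raises(DataError):
            scca_fit(X, Y, PenaltyPair(1.5, 1.2))


class TestCanonicalCorrelation:
    def test_zero_vector_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        Y = rng.standard_normal((10, 2))
        with pytest.raises(DataError):
            canonical_correlation(X, Y, np.ones(3), np.zeros(2))

    def test_affine_transform_gives_unit_correlation(self, rng):
        X = rng.standard_normal((20, 3))
        u = np.array([0.3, -0.5, 0.2])
        Y = (2.0 * (X @ u) + 1.0)[:, None]
        assert canonical_correlation(X, Y, u, np.array([1.0])) == pytest.approx(1.0)

    def test_planted_rho_matches_closed_form_attenuation(self):
        """Sample canonical correlation at the oracle loadings versus the
        closed-form population value under median-split binarization."""
        lam, sd, n = 10.0, 1.0, 500
        X, Y, truth = generate_coupled_dataset(
            n, 40, 20, 5, 4, latent_strength=lam, noise_sd=sd,
            response_mode="binary", seed=77,
        )
        rho_hat = canonical_correlation(X, Y, truth.u_true, truth.v_true)
        rho_pop = _binary_rho_population(truth.v_true, lam, sd)
        assert rho_hat == pytest.approx(rho_pop, abs=0.05)


def _binary_rho_population(v_true, lam, sd):
    """Population corr of (X u_true, Y v_true) for the binary generator.

    X u_true = lam z + sd xi with xi standard normal. Each support response
    y_j = 1{c_j > 0} with c_j = lam v_j z + sd eps_j; E[c 1{c>0}] identities
    give cov(z, y_j) = phi(0) lam v_j / s_j, var(y_j) = 1/4, and
    cov(y_j, y_k) = arcsin(rho_jk) / (2 pi) for the latent correlation
    rho_jk.
    """
    phi0 = 1.0 / np.sqrt(2 * np.pi)
    idx = np.flatnonzero(v_true)
    v = v_true[idx]
    s = np.sqrt(lam**2 * v**2 + sd**2)
    cov_zy = phi0 * lam * v / s
    cov_T = lam * np.sum(v * cov_zy)
    var_X = lam**2 + sd**2
    var_T = np.sum(v**2) / 4.0
    for a in range(len(v)):
        for b in range(len(v)):
            if a == b:
                continue
            r_ab = (lam**2 * v[a] * v[b]) / (s[a] * s[b])
            var_T += v[a] * v[b] * np.arcsin(r_ab) / (2 * np.pi)
    return cov_T / np.sqrt(var_X * var_T)
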