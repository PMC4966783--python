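import numpy as np
import pytest

import indicar as ic
from indicar.inference import (WorkingModel, blup_and_fixed_solutions,
                               build_working_model, effective_df_random,
                               fixed_covariance_from_working)
from indicar.spatial import build_structure_matrix

from oracles import dense_fixed_covariance, henderson_solve


def random_working_model(seed, n, M, q=1, sigma2=0.2, lam=0.5):
    """A synthetic working LMM (weights/pseudo-response need not be at a
    converged fit: the block identities hold for any positive weights)."""
    rng = np.random.default_rng(seed)
    rows = max(2, int(np.sqrt(M)))
    adj = ic.lattice_adjacency(rows, M // rows)
    M = adj.n_regions
    g = rng.integers(0, M, n)
    g[:M] = np.arange(M)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    U = rng.standard_normal((M, q))
    R = build_structure_matrix(adj)
    D = ic.leroux_covariance(ic.LerouxParams(sigma2, lam), R)
    return WorkingModel(
        X=X, U=U, region_index=g, n_regions=M,
        weights=rng.uniform(0.2, 3.0, n),
        y_pseudo=rng.normal(size=n), D=D,
    ), R


class TestWoodburyCovariance:
    @pytest.mark.parametrize("seed,n,M", [(0, 60, 9), (1, 200, 16),
                                          (2, 500, 25)])
    def test_equals_dense_inverse(self, seed, n, M):
        work, _ = random_working_model(seed, n, M)
        Q = fixed_covariance_from_working(work)
        Qd = dense_fixed_covariance(work.X, work.U, work.region_index,
                                    work.n_regions, work.weights, work.D)
        assert np.max(np.abs(Q - Qd)) < 1e-8

    def test_zero_random_effect_reduces_to_glm_covariance(self):
        work, _ = random_working_model(3, 100, 9)
        work.D = np.zeros_like(work.D)
        Q = fixed_covariance_from_working(work)
        Z = np.zeros((100, work.n_regions))
        Z[np.arange(100), work.region_index] = 1.0
        C = np.hstack([work.X, Z @ work.U])
        expected = np.linalg.inv((C.T * work.weights) @ C)
        np.testing.assert_allclose(Q, expected, atol=1e-10)

    def test_symmetric_positive_definite(self):
        work, _ = random_working_model(4, 150, 16)
        Q = fixed_covariance_from_working(work)
        np.testing.assert_allclose(Q, Q.T, atol=1e-10)
        np.linalg.cholesky(Q)

    def test_dominates_naive_glm_covariance(self, small_instance, small_fit):
        # accounting for the estimated group effects can only add variance:
        # Q minus the naive Step-2 covariance is positive semi-definite
        data, regions, adj, _ = small_instance
        fit = small_fit
        region_lin = regions.U @ fit.gamma + fit.b
        glm = ic.fit_poisson_glm(data.y, data.X,
                                 region_lin[data.region_index])
        p = data.p
        diff = fit.cov_fixed[:p, :p] - glm.cov_naive
        assert np.linalg.eigvalsh(0.5 * (diff + diff.T)).min() > -1e-10


class TestBlupSolutions:
    def test_matches_henderson_equations(self):
        work, _ = random_working_model(5, 120, 9)
        beta, gamma, b = blup_and_fixed_solutions(work)
        beta_o, gamma_o, b_o = henderson_solve(
            work.X, work.U, work.region_index, work.n_regions,
            work.weights, work.D, work.y_pseudo)
        np.testing.assert_allclose(beta, beta_o, atol=1e-9)
        np.testing.assert_allclose(gamma, gamma_o, atol=1e-9)
        np.testing.assert_allclose(b, b_o, atol=1e-9)

    def test_zero_random_effect_gives_wls_and_zero_blup(self):
        work, _ = random_working_model(6, 80, 9)
        work.D = np.zeros_like(work.D)
        beta, gamma, b = blup_and_fixed_solutions(work)
        np.testing.assert_allclose(b, 0.0, atol=1e-12)
        Z = np.zeros((80, work.n_regions))
        Z[np.arange(80), work.region_index] = 1.0
        C = np.hstack([work.X, Z @ work.U])
        coef = np.linalg.solve((C.T * work.weights) @ C,
                               (C.T * work.weights) @ work.y_pseudo)
        np.testing.assert_allclose(np.concatenate([beta, gamma]), coef,
                                   atol=1e-10)

    def test_reproduces_converged_backfit(self, small_instance, small_fit):
        data, regions, adj, _ = small_instance
        fit = small_fit
        R = build_structure_matrix(adj)
        work = build_working_model(data, regions, fit.beta, fit.gamma,
                                   fit.b, fit.theta, R)
        beta, gamma, b = blup_and_fixed_solutions(work)
        assert np.max(np.abs(beta - fit.beta)) < 1e-4
        assert np.max(np.abs(gamma - fit.gamma)) < 1e-4
        assert np.max(np.abs(b - fit.b)) < 1e-4


class TestBlupCovariance:
    def test_diagonal_closed_form_when_independent(self):
        R = np.zeros((3, 3))
        w = np.array([2.0, 5.0, 0.5])
        theta = ic.LerouxParams(0.25, 0.0)
        cov = ic.blup_covariance(w, R, theta)
        np.testing.assert_allclose(np.diag(cov), 1.0 / (w + 4.0))
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0,
                                   atol=1e-12)

    def test_matches_dense_inverse(self):
        R = build_structure_matrix(ic.lattice_adjacency(3, 3))
        rng = np.random.default_rng(8)
        w = rng.uniform(1, 10, 9)
        theta = ic.LerouxParams(0.3, 0.6)
        cov = ic.blup_covariance(w, R, theta)
        dense = np.linalg.inv(ic.leroux_precision(theta, R) + np.diag(w))
        np.testing.assert_allclose(cov, dense, atol=1e-10)
        np.linalg.cholesky(cov)

    def test_complete_shrinkage_limit(self):
        R = build_structure_matrix(ic.lattice_adjacency(2, 2))
        w = np.full(4, 3.0)
        cov = ic.blup_covariance(w, R, ic.LerouxParams(1e-10, 0.0))
        assert np.max(np.abs(cov)) < 1e-9


class TestConditionalAic:
    def test_effective_df_in_range_and_monotone_in_sigma2(self):
        R = build_structure_matrix(ic.lattice_adjacency(3, 3))
        w = np.full(9, 5.0)
        dfs = [effective_df_random(w, R, ic.LerouxParams(s2, 0.4))
               for s2 in (1e-8, 0.05, 0.5, 5.0)]
        assert all(0 <= d < 9 for d in dfs)
        assert np.all(np.diff(dfs) > 0)

    def test_reduces_to_glm_aic_without_random_effect(self, small_instance):
        data, regions, adj, _ = small_instance
        opts = ic.FitOptions(fix_theta=ic.LerouxParams(1e-10, 0.0))
        fit = ic.fit_indicar(data, regions, adj, opts)
        y = data.y.astype(float)
        glm_mu = ic.fit_poisson_glm(data.y, data.X).fitted_mu
        # gamma ~ 0 with a tiny prior on b, so mu is close to the GLM fit
        ll = np.sum(np.where(y > 0, y * np.log(fit.mu), 0.0)) - fit.mu.sum()
        expected = -2 * ll + 2 * (data.p + regions.q)
        assert fit.caic == pytest.approx(expected, abs=1e-4)

    def test_noise_covariate_costs_about_one_df(self, small_instance):
        data, regions, adj, _ = small_instance
        theta = ic.LerouxParams(0.16, 0.5)
        base = ic.fit_indicar(data, regions, adj,
                              ic.FitOptions(fix_theta=theta))
        rng = np.random.default_rng(55)
        noisy = ic.RegionTable(
            U=np.column_stack([regions.U, rng.standard_normal(regions.M)]),
            region_labels=regions.region_labels)
        bigger = ic.fit_indicar(data, noisy, adj,
                                ic.FitOptions(fix_theta=theta))
        y = data.y.astype(float)

        def rho(fit, q):
            ll = (np.sum(np.where(y > 0, y * np.log(fit.mu), 0.0))
                  - fit.mu.sum())
            return (fit.caic + 2 * ll) / 2

        assert rho(bigger, 2) - rho(base, 1) == pytest.approx(1.0, abs=0.2)
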