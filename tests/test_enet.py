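import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

import ssbl._updates as upd
from ssbl.core import gaussian_posterior
from ssbl.enet import (
    ENETConfig,
    ENETHyperState,
    _alpha1_update,
    _gamma_update_column,
    _k_update,
    enet_alpha1_objective,
    enet_effective_variance,
    enet_fit,
    enet_gamma_objective,
    enet_k_objective,
    enet_mixture_marginal,
    enet_update_hyperparameters,
)


class TestEffectiveVariance:
    def test_no_truncation_is_ridge(self, rng):
        pv = enet_effective_variance(rng.uniform(0.5, 3.0, 7), alpha1=1.0, k=0.0)
        np.testing.assert_array_equal(pv.lam_bar, 1.0)
        np.testing.assert_array_equal(pv.lam, 0.5)

    def test_paper_parameterization(self):
        # alpha1 = 1, alpha2 = 2 -> k = alpha2^2 / (4 alpha1) = 1
        pv = enet_effective_variance(np.array([2.0]), alpha1=1.0, k=1.0)
        assert pv.lam_bar[0] == pytest.approx(0.5)
        assert pv.lam[0] == pytest.approx(0.25)

    def test_truncation_limit_prunes(self):
        k = 0.8
        pv = enet_effective_variance(np.array([k * (1 + 1e-12)]), 1.0, k)
        assert pv.lam[0] == 0.0

    def test_floor_clip(self):
        # raw factor between floor/2 and floor is clipped up to the floor
        k = 1.0
        gamma = np.array([k / (1 - 0.7e-6)])
        pv = enet_effective_variance(gamma, 1.0, k, floor=1e-6)
        assert pv.lam_bar[0] == pytest.approx(1e-6)

    def test_support_violation(self):
        with pytest.raises(ValueError):
            enet_effective_variance(np.array([0.5]), 1.0, 1.0)


class TestMixtureMarginal:
    def test_untruncated_collapses_to_normal(self):
        for j in [0.0, 0.7, 1.5]:
            val = enet_mixture_marginal(j, 1.3, 0.0)
            assert val == pytest.approx(norm.pdf(j, scale=np.sqrt(1 / 2.6)),
                                        abs=1e-8)

    def test_symmetry(self):
        for j in [0.3, 1.1]:
            assert enet_mixture_marginal(j, 0.8, 0.4) == pytest.approx(
                enet_mixture_marginal(-j, 0.8, 0.4), rel=1e-12)

    def test_matches_directly_normalized_density(self):
        alpha1, alpha2 = 1.0, 1.0
        k = alpha2 ** 2 / (4 * alpha1)
        z, _ = integrate.quad(
            lambda x: np.exp(-alpha1 * x * x - alpha2 * abs(x)),
            -np.inf, np.inf)
        for j in [0.0, 0.5, 1.0, 2.0]:
            target = np.exp(-alpha1 * j * j - alpha2 * abs(j)) / z
            assert enet_mixture_marginal(j, alpha1, k) == pytest.approx(
                target, abs=1e-6)


def _grid_argmin(fun, lo=1e-6, hi=1e6, n=1000):
    grid = np.geomspace(lo, hi, n)
    vals = np.asarray(fun(grid), dtype=float)
    vals = np.where(np.isfinite(vals), vals, np.inf)
    i = int(np.argmin(vals))
    return float(grid[i]), float(vals[i])


class TestCoordinateUpdates:
    def test_gamma_update_matches_grid_oracle(self, rng):
        for _ in range(20):
            m = float(rng.uniform(0.01, 5.0))
            alpha1 = float(rng.uniform(0.1, 10.0))
            k = float(rng.uniform(0.05, 2.0))
            gamma = _gamma_update_column(np.array([m]), alpha1, k,
                                         np.array([k + 1.0]), 1e-9)[0]
            fun = lambda g: enet_gamma_objective(g, m, alpha1, k)
            x_grid, f_grid = _grid_argmin(fun, lo=k * (1 + 1e-9), hi=k + 1e6)
            assert fun(gamma) <= f_grid + 1e-9 * (1 + abs(f_grid))

    def test_beta_update_residual_only(self, rng):
        v = rng.standard_normal(6)
        assert upd.beta_update(float(v @ v), 6) == pytest.approx(v @ v / 6)
        x_grid, f_grid = _grid_argmin(lambda b: upd.beta_objective(b, v @ v, 6))
        b = upd.beta_update(float(v @ v), 6)
        assert upd.beta_objective(b, v @ v, 6) <= f_grid + 1e-12

    def test_alpha1_hand_stationarity(self, rng):
        # with lam_bar = 1 (k = 0) the stationary point of the coordinate
        # restriction of the objective is n / (2 sum mu^2)
        mu2 = rng.uniform(0.1, 1.0, 8)
        lam_bar = np.ones(8)
        a1 = _alpha1_update(mu2, lam_bar)
        assert a1 == pytest.approx(8 / (2 * mu2.sum()), rel=1e-12)
        x_grid, f_grid = _grid_argmin(
            lambda a: np.array([enet_alpha1_objective(x, mu2, lam_bar)
                                for x in np.atleast_1d(a)]))
        assert enet_alpha1_objective(a1, mu2, lam_bar) <= f_grid + 1e-12

    def test_alpha1_update_matches_grid_oracle(self, rng):
        m = rng.uniform(0.01, 2.0, 12)
        lam_bar = rng.uniform(0.05, 1.0, 12)
        a1 = _alpha1_update(m, lam_bar)
        _, f_grid = _grid_argmin(
            lambda a: np.array([enet_alpha1_objective(x, m, lam_bar)
                                for x in np.atleast_1d(a)]))
        assert enet_alpha1_objective(a1, m, lam_bar) <= f_grid + 1e-12

    def test_k_update_matches_grid_oracle(self, rng):
        config = ENETConfig()
        for _ in range(5):
            gamma = rng.uniform(0.5, 5.0, 30)
            m = rng.uniform(1e-4, 1.0, 30)
            alpha1 = float(rng.uniform(0.5, 5.0))
            k_new = _k_update(0.2, gamma, m, alpha1, config)
            fun = lambda k: enet_k_objective(k, gamma, m, alpha1,
                                             config.tau, config.upsilon)
            _, f_grid = _grid_argmin(fun, lo=1e-6, hi=1e6)
            assert fun(k_new) <= f_grid + 1e-9 * (1 + abs(f_grid))

    def test_sweep_matches_grid_on_random_instance(self, rng):
        # every minimized coordinate of a full sweep beats the 1000-point
        # grid search of its own coordinate objective (4 x 10 x 3 instance)
        from tests.conftest import random_problem
        K, V, _ = random_problem(rng, n_sensors=4, n_gen=10, n_times=3)
        config = ENETConfig()
        state = ENETHyperState(gamma=np.full((10, 3), 1.3),
                               alpha1=np.full(3, 2.0), k=np.full(3, 0.3),
                               beta=np.full(3, 0.5))
        lams = [enet_effective_variance(state.gamma[:, t], state.alpha1[t],
                                        state.k[t]) for t in range(3)]
        posts = [gaussian_posterior(K, V[:, t], lams[t], state.beta[t])
                 for t in range(3)]
        new = enet_update_hyperparameters(state, posts, V, K, config)
        for t in range(3):
            m = posts[t].mu ** 2 + posts[t].sigma_diag
            # gamma coordinates (spot check a few)
            for i in [0, 4, 9]:
                fun = lambda g: enet_gamma_objective(g, m[i], state.alpha1[t],
                                                     state.k[t])
                _, f_grid = _grid_argmin(fun, lo=state.k[t] * (1 + 1e-9),
                                         hi=state.k[t] + 1e6)
                # the sweep updates gamma first, at the incoming alpha1/k
                gam_first = _gamma_update_column(m, state.alpha1[t], state.k[t],
                                                 state.gamma[:, t], 1e-6)
                assert fun(gam_first[i]) <= f_grid + 1e-9 * (1 + abs(f_grid))
            # beta coordinate
            rpt = float(posts[t].residual @ posts[t].residual) + posts[t].trace_ksk
            _, f_grid = _grid_argmin(lambda b: upd.beta_objective(b, rpt, 4))
            assert upd.beta_objective(new.beta[t], rpt, 4) <= f_grid + 1e-12

    def test_beta_with_zero_posterior(self):
        assert upd.beta_update(4.0, 4) == pytest.approx(1.0)


class TestFit:
    def test_identity_recovery(self):
        K = np.eye(5)
        J = np.zeros((5, 1))
        J[2] = 1.0
        res = enet_fit(K @ J, K, ENETConfig(max_iter=60))
        est = np.abs(res.estimate.J[:, 0])
        assert est.argmax() == 2
        assert np.delete(est, 2).max() <= 1e-3 * est.max()

    def test_zero_data(self):
        K = np.eye(4)
        res = enet_fit(np.zeros((4, 2)), K, ENETConfig(max_iter=10))
        assert np.all(res.estimate.J == 0)
        assert np.all(res.hyper_trajectory[-1].k > 0)  # sparsity maximal

    def test_objective_monotone(self, rng):
        from tests.conftest import random_problem
        K, V, _ = random_problem(rng)
        res = enet_fit(V, K, ENETConfig(max_iter=20))
        diffs = np.diff(res.objective_trajectory)
        assert np.all(diffs <= 1e-8 * (1 + np.abs(res.objective_trajectory[:-1])))

    def test_default_benchmark_converges_within_30(self):
        from ssbl.simulate import SimulationConfig, build_assets, simulate_trial
        config = SimulationConfig(S=300, N=32, T=101, seed=3)
        assets = build_assets(config)
        rec, _, K_inv = simulate_trial(config, 77, assets=assets)
        res = enet_fit(rec, K_inv)
        assert res.converged
        assert res.n_iter <= 30

    def test_ridge_limit(self, rng):
        K = rng.standard_normal((6, 10))
        V = rng.standard_normal((6, 3))
        res = enet_fit(V, K, ENETConfig(learn_k=False, max_iter=200, tol=1e-12))
        state = res.hyper_trajectory[-1]
        for t in range(3):
            ridge = np.linalg.solve(
                K.T @ K + 2 * state.alpha1[t] * state.beta[t] * np.eye(10),
                K.T @ V[:, t])
            np.testing.assert_allclose(res.estimate.J[:, t], ridge, atol=1e-8)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="sensors"):
            enet_fit(rng.standard_normal((5, 2)), rng.standard_normal((4, 8)))


class TestSparsityMonotonicity:
    def test_pruned_count_nondecreasing_in_k(self, rng):
        gamma = rng.uniform(0.1, 3.0, 200)
        counts = []
        for k in np.linspace(0.0, 0.95 * gamma.min() / (1 - 1e-6), 10):
            pv = enet_effective_variance(np.maximum(gamma, k * (1 + 1e-9)),
                                         1.0, k)
            counts.append(int((pv.lam_bar < 0.01).sum()))
        assert np.all(np.diff(counts) >= 0)
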