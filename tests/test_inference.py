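"""Coordinate-update correctness: conjugate reductions, grid-search and
quadrature oracles, ascent of the surrogate objective, reproducibility."""

import copy

import numpy as np
import pytest
from scipy.special import gammaln

import stimtag as st
from stimtag.inference import (
    FitData,
    ModelConfig,
    compute_elbo,
    init_state,
    run_forward_backward,
    sweep,
    update_baseline,
    update_baseline_hyperparams,
    update_chain_params,
    update_covariate_gains,
    update_feature_gains,
    update_feature_hyperparams,
    update_hyperparams,
    update_overdispersion,
)
from stimtag.simulate import ObservationTable


def make_data(rng, U=3, T=12, K=0, R=0, rate=2.0, reps=1):
    t = np.repeat(np.arange(T), U * reps)
    u = np.tile(np.repeat(np.arange(U), reps), T)
    N = rng.poisson(rate, size=t.size)
    table = ObservationTable(t, u, N, T, U)
    x = (rng.random((T, R)) < 0.5).astype(float) if R else None
    return FitData(table, x)


def prepared_state(data, config, seed=0, n_sweeps=2):
    state = init_state(data, config, np.random.default_rng(seed))
    for _ in range(n_sweeps):
        sweep(state, data, config)
    return state


class TestBaselineUpdate:
    def test_conjugate_gamma_poisson_reduction(self):
        # K = R = 0, no overdispersion, fixed prior: the exact textbook update
        rng = np.random.default_rng(0)
        data = make_data(rng, U=4, T=25)
        config = ModelConfig(
            n_features=0, hierarchical_baseline=False, overdispersion=False,
            prior_baseline=(2.5, 1.5),
        )
        state = init_state(data, config, rng)
        update_baseline(state, data, config)
        np.testing.assert_allclose(state.alpha0, 2.5 + data.sum_N_per_unit)
        np.testing.assert_allclose(state.beta0, 1.5 + data.obs_per_unit)

    def test_single_observation_shrinkage(self):
        table = ObservationTable([0], [0], [7], 1, 1)
        data = FitData(table)
        config = ModelConfig(
            n_features=0, hierarchical_baseline=False, overdispersion=False,
            prior_baseline=(1.0, 1.0),
        )
        state = init_state(data, config, np.random.default_rng(0))
        update_baseline(state, data, config)
        post_mean = state.alpha0[0] / state.beta0[0]
        assert 1.0 < post_mean < 7.0

    def test_empty_unit_keeps_prior(self):
        table = ObservationTable([0, 1], [0, 0], [3, 1], 2, 2)  # unit 1 unseen
        data = FitData(table)
        config = ModelConfig(
            n_features=0, hierarchical_baseline=False, overdispersion=False,
            prior_baseline=(2.0, 3.0),
        )
        state = init_state(data, config, np.random.default_rng(0))
        update_baseline(state, data, config)
        assert state.alpha0[1] == pytest.approx(2.0)
        assert state.beta0[1] == pytest.approx(3.0)

    def test_maximizes_elbo_over_grid(self):
        rng = np.random.default_rng(1)
        data = make_data(rng, U=2, T=4, rate=1.0)
        config = ModelConfig(n_features=0, overdispersion=False)
        state = prepared_state(data, config)
        update_baseline(state, data, config)
        best = compute_elbo(state, data, config)
        for fs in np.linspace(0.7, 1.4, 9):
            for fr in np.linspace(0.7, 1.4, 9):
                trial = copy.deepcopy(state)
                trial.alpha0[0] = state.alpha0[0] * fs
                trial.beta0[0] = state.beta0[0] * fr
                assert compute_elbo(trial, data, config) <= best + 1e-9


class TestFeatureGainUpdate:
    def _config(self, **kw):
        return ModelConfig(n_features=1, overdispersion=False, **kw)

    def test_chain_never_on_returns_prior(self):
        rng = np.random.default_rng(2)
        data = make_data(rng, U=3, T=10)
        config = self._config()
        state = prepared_state(data, config)
        state.chain_posteriors[0].xi[:, 1] = 0.0
        state.chain_posteriors[0].xi[:, 0] = 1.0
        state.refresh_f_factor(0)
        update_feature_gains(state, data, config, 0)
        ec = state.cz[0, 0] / state.cz[0, 1]
        ed = state.dz[0, 0] / state.dz[0, 1]
        np.testing.assert_allclose(state.alpha_z[:, 0], ec)
        np.testing.assert_allclose(state.beta_z[:, 0], ec * ed)

    def test_chain_always_on_maximizes_elbo_over_grid(self):
        rng = np.random.default_rng(3)
        data = make_data(rng, U=1, T=4, rate=3.0)
        config = self._config()
        state = prepared_state(data, config)
        state.chain_posteriors[0].xi[:, 1] = 1.0
        state.chain_posteriors[0].xi[:, 0] = 0.0
        state.refresh_f_factor(0)
        update_feature_gains(state, data, config, 0)
        best = compute_elbo(state, data, config)
        for fs in np.linspace(0.8, 1.3, 7):
            for fr in np.linspace(0.8, 1.3, 7):
                trial = copy.deepcopy(state)
                trial.alpha_z[0, 0] = state.alpha_z[0, 0] * fs
                trial.beta_z[0, 0] = state.beta_z[0, 0] * fr
                trial.refresh_f_factor(0)
                assert compute_elbo(trial, data, config) <= best + 1e-9

    def test_out_of_range_feature_rejected(self):
        rng = np.random.default_rng(4)
        data = make_data(rng, U=2, T=5)
        config = self._config()
        state = prepared_state(data, config)
        with pytest.raises(IndexError):
            update_feature_gains(state, data, config, 3)


class TestCovariateUpdate:
    def test_all_zero_covariate_keeps_prior(self):
        rng = np.random.default_rng(5)
        data = make_data(rng, U=2, T=8, R=1)
        data.x[:] = 0.0
        config = ModelConfig(n_features=0, overdispersion=False,
                             prior_covariate=(1.5, 2.0))
        # rebuild grouping for the zeroed covariate
        data = FitData(
            ObservationTable(data.t, data.u, data.N.astype(int), data.T, data.U),
            data.x,
        )
        state = prepared_state(data, config)
        update_covariate_gains(state, data, config)
        np.testing.assert_allclose(state.alpha_x, 1.5)
        np.testing.assert_allclose(state.beta_x, 2.0)

    def test_binary_covariate_matches_closed_form(self):
        rng = np.random.default_rng(6)
        data = make_data(rng, U=3, T=20, R=1)
        config = ModelConfig(n_features=0, overdispersion=False,
                             prior_covariate=(1.0, 1.0))
        state = prepared_state(data, config)
        pre = copy.deepcopy(state)
        update_covariate_gains(state, data, config)
        # closed-form conjugate update for x in {0, 1}
        xv = data.x[data.t, 0]
        w = pre.e_theta(data.M) * pre.e_baseline()[data.u] * (
            pre.cache_F() * pre.G_excluding(0)
        )[data.t, data.u]
        for u in range(data.U):
            sel = data.u == u
            a_exp = 1.0 + np.sum(data.N[sel] * xv[sel])
            b_exp = 1.0 + np.sum(w[sel & (xv == 1.0)])
            assert state.alpha_x[u, 0] == pytest.approx(a_exp, rel=1e-6)
            assert state.beta_x[u, 0] == pytest.approx(b_exp, rel=1e-6)

    def test_maximizes_elbo_over_grid(self):
        rng = np.random.default_rng(7)
        data = make_data(rng, U=1, T=4, R=1, rate=3.0)
        config = ModelConfig(n_features=0, overdispersion=False)
        state = prepared_state(data, config)
        update_covariate_gains(state, data, config)
        best = compute_elbo(state, data, config)
        for fs in np.linspace(0.7, 1.4, 9):
            for fr in np.linspace(0.7, 1.4, 9):
                trial = copy.deepcopy(state)
                trial.alpha_x[0, 0] = state.alpha_x[0, 0] * fs
                trial.beta_x[0, 0] = state.beta_x[0, 0] * fr
                trial.refresh_g_factor(0, data.x[:, 0])
                assert compute_elbo(trial, data, config) <= best + 1e-9


class TestHyperparameterUpdate:
    def test_c_shape_is_prior_plus_half_per_unit(self):
        rng = np.random.default_rng(8)
        for U in (1, 5, 17):
            lam_shape = rng.uniform(1, 20, U)
            lam_rate = rng.uniform(1, 20, U)
            c, d = np.array([2.0, 1.0]), np.array([1.0, 1.0])
            c_new, _ = update_hyperparams(
                lam_shape, lam_rate, c, d, (3.0, 2.0), (1.0, 1.0)
            )
            assert c_new[0] == pytest.approx(3.0 + U / 2.0)

    def test_no_units_returns_priors(self):
        c_new, d_new = update_hyperparams(
            np.zeros(0), np.zeros(0),
            np.array([5.0, 2.0]), np.array([4.0, 3.0]),
            (3.0, 2.0), (1.5, 0.5),
        )
        np.testing.assert_allclose(c_new, [3.0, 2.0])
        np.testing.assert_allclose(d_new, [1.5, 0.5])

    def test_d_mean_against_quadrature_oracle(self):
        # Exact small-U posterior of d (c integrated numerically, no Stirling
        # bound) vs. the bound-based coordinate updates, with the child gains
        # pinned at near-point-mass values.
        rng = np.random.default_rng(9)
        U = 5
        lam = rng.gamma(2.0, 1.0, U)
        big = 1e7
        lam_shape, lam_rate = big * np.ones(U), big / lam
        a_c, b_c, a_d, b_d = 2.0, 1.0, 2.0, 1.0
        c = np.array([a_c, b_c])
        d = np.array([a_d, b_d])
        for _ in range(400):
            c, d = update_hyperparams(
                lam_shape, lam_rate, c, d, (a_c, b_c), (a_d, b_d)
            )
        vb_mean_d = d[0] / d[1]

        S, P = lam.sum(), np.log(lam).sum()
        cs = np.linspace(1e-3, 200.0, 400_000)
        logw = (
            (a_c - 1) * np.log(cs) - b_c * cs
            + U * cs * np.log(cs) - U * gammaln(cs) + (cs - 1) * P
            + gammaln(a_d + U * cs) - (a_d + U * cs) * np.log(b_d + cs * S)
        )
        w = np.exp(logw - logw.max())
        exact_mean_d = np.trapezoid(
            w * (a_d + U * cs) / (b_d + cs * S), cs
        ) / np.trapezoid(w, cs)
        assert vb_mean_d == pytest.approx(exact_mean_d, rel=0.15)


class TestOverdispersionUpdate:
    def test_theta_concentrates_when_count_matches_rate(self):
        rng = np.random.default_rng(10)
        T, U = 6, 1
        lam = 5.0
        table = ObservationTable(
            np.arange(T), np.zeros(T, int), np.full(T, int(lam)), T, U
        )
        data = FitData(table)
        config = ModelConfig(n_features=0, hierarchical_baseline=False,
                             prior_baseline=(lam * 1e8, 1e8),
                             prior_overdispersion=(1e6, 10.0))
        state = init_state(data, config, rng)
        update_overdispersion(state, data, config)
        e_theta = state.e_theta(data.M)
        np.testing.assert_allclose(e_theta, 1.0, atol=1e-3)
        var = state.theta_shape / state.theta_rate**2
        assert np.all(var < 1e-4)

    def test_disabled_theta_is_unity(self):
        rng = np.random.default_rng(11)
        data = make_data(rng, U=2, T=5)
        config = ModelConfig(n_features=0, overdispersion=False)
        state = init_state(data, config, rng)
        update_overdispersion(state, data, config)
        np.testing.assert_allclose(state.e_theta(data.M), 1.0)


class TestChainUpdates:
    def test_uninformative_gains_give_flat_evidence(self):
        rng = np.random.default_rng(12)
        data = make_data(rng, U=3, T=8)
        config = ModelConfig(n_features=1, overdispersion=False)
        state = prepared_state(data, config)
        big = 1e9
        state.alpha_z[:, 0] = big
        state.beta_z[:, 0] = big  # gain pinned at 1
        state.refresh_f_factor(0)
        ev = st.inference.expected_log_evidence(state, data, 0)
        np.testing.assert_allclose(
            ev.log_evidence[:, 1], ev.log_evidence[:, 0], atol=1e-6
        )

    def test_hand_computed_single_observation_evidence(self):
        # one unit, one tag, one observation N = 3 at t = 0; all expectations
        # written out by hand from the gamma parameters
        from scipy.special import digamma

        table = ObservationTable([0], [0], [3], 2, 1)
        data = FitData(table)
        config = ModelConfig(n_features=1, overdispersion=False)
        state = init_state(data, config, np.random.default_rng(0))
        state.alpha0[:], state.beta0[:] = 6.0, 3.0    # E[lam0] = 2
        state.alpha_z[:], state.beta_z[:] = 4.0, 2.0  # E[lamz] = 2
        state.refresh_f_factor(0)
        ev = st.inference.expected_log_evidence(state, data, 0)
        eta_on = 3.0 * (digamma(4.0) - np.log(2.0)) - 1.0 * 2.0 * 2.0
        eta_off = -2.0
        assert ev.log_evidence[0, 1] == pytest.approx(eta_on, abs=1e-12)
        assert ev.log_evidence[0, 0] == pytest.approx(eta_off, abs=1e-12)
        np.testing.assert_allclose(ev.log_evidence[1], 0.0)

    def test_no_observation_bins_get_zero_evidence(self):
        table = ObservationTable([0, 2], [0, 0], [1, 2], 4, 1)
        data = FitData(table)
        config = ModelConfig(n_features=1, overdispersion=False)
        state = prepared_state(data, config)
        ev = st.inference.expected_log_evidence(state, data, 0)
        np.testing.assert_allclose(ev.log_evidence[[1, 3]], 0.0)

    def test_dirichlet_counts_from_uniform_two_slice(self):
        rng = np.random.default_rng(13)
        data = make_data(rng, U=1, T=2, K=0)
        config = ModelConfig(n_features=1, overdispersion=False)
        state = init_state(data, config, rng)
        state.chain_posteriors[0].xi[:] = 0.5
        state.chain_posteriors[0].Xi[:] = 0.25
        update_chain_params(state, config, 0)
        np.testing.assert_allclose(state.A_counts[0], 1.0 + 0.25)
        np.testing.assert_allclose(state.pi_counts[0], 1.0 + 0.5)

    def test_fully_observed_chain_recovers_dirichlet_posterior(self):
        # degenerate xi/Xi == a fully observed chain: counts are exact
        rng = np.random.default_rng(14)
        z = (rng.random(30) < 0.5).astype(int)
        data = make_data(rng, U=1, T=30)
        config = ModelConfig(n_features=1, overdispersion=False)
        state = init_state(data, config, rng)
        post = state.chain_posteriors[0]
        post.xi[:] = np.column_stack([1 - z, z])
        post.Xi[:] = 0.0
        for t in range(29):
            post.Xi[t, z[t], z[t + 1]] = 1.0
        update_chain_params(state, config, 0)
        expected = np.ones((2, 2))
        for t in range(29):
            expected[z[t], z[t + 1]] += 1.0
        np.testing.assert_allclose(state.A_counts[0], expected)


class TestObjective:
    def test_zero_for_priors_and_no_data(self):
        table = ObservationTable(
            np.zeros(0, int), np.zeros(0, int), np.zeros(0, int), 5, 3
        )
        data = FitData(table)
        config = ModelConfig(n_features=0, hierarchical_baseline=False,
                             overdispersion=False)
        state = init_state(data, config, np.random.default_rng(0))
        assert compute_elbo(state, data, config) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_every_update_is_an_ascent_step(self, seed):
        rng = np.random.default_rng(100 + seed)
        data = make_data(rng, U=4, T=30, K=2, R=1, rate=1.0)
        config = ModelConfig(n_features=2, seed=seed)
        state = init_state(data, config, np.random.default_rng(seed))
        sweep(state, data, config)
        L = compute_elbo(state, data, config)
        steps = [
            lambda: update_baseline(state, data, config),
            lambda: update_baseline_hyperparams(state, data, config),
            lambda: update_feature_gains(state, data, config, 0),
            lambda: update_feature_hyperparams(state, data, config, 0),
            lambda: update_chain_params(state, config, 0),
            lambda: run_forward_backward(state, data, 0),
            lambda: update_feature_gains(state, data, config, 1),
            lambda: update_feature_hyperparams(state, data, config, 1),
            lambda: update_chain_params(state, config, 1),
            lambda: run_forward_backward(state, data, 1),
            lambda: update_covariate_gains(state, data, config),
            lambda: update_overdispersion(state, data, config),
        ]
        for _ in range(3):
            for do in steps:
                do()
                L_new = compute_elbo(state, data, config)
                assert L_new >= L - 1e-4 * abs(L)
                L = L_new

    def test_fit_improves_on_initialization(self):
        rng = np.random.default_rng(15)
        params = st.benchmark_preset(seed=2, scale=0.03)
        table, truth = st.simulate_dataset(params, seed=2)
        config = ModelConfig(n_features=2, n_restarts=1, max_iter=10, seed=0)
        data = FitData(table, truth.covariates)
        state0 = init_state(data, config, np.random.default_rng(0))
        sweep(state0, data, config)
        L0 = compute_elbo(state0, data, config)
        result = st.fit(table, covariates=truth.covariates, config=config)
        assert result.elbo > L0


class TestFitContract:
    def test_same_seed_bit_identical(self):
        params = st.benchmark_preset(seed=5, scale=0.04)
        table, truth = st.simulate_dataset(params, seed=5)
        config = ModelConfig(n_features=2, n_restarts=2, max_iter=12, seed=9)
        r1 = st.fit(table, covariates=truth.covariates, config=config)
        r2 = st.fit(table, covariates=truth.covariates, config=config)
        assert np.array_equal(r1.elbo_trace, r2.elbo_trace)
        assert np.array_equal(r1.state.alpha_z, r2.state.alpha_z)
        assert np.array_equal(r1.state.beta0, r2.state.beta0)
        assert np.array_equal(
            r1.state.chain_posteriors[0].xi, r2.state.chain_posteriors[0].xi
        )

    def test_best_restart_attains_max(self):
        params = st.benchmark_preset(seed=6, scale=0.03)
        table, truth = st.simulate_dataset(params, seed=6)
        config = ModelConfig(n_features=2, n_restarts=3, max_iter=10, seed=3)
        result = st.fit(table, covariates=truth.covariates, config=config)
        assert result.elbo == pytest.approx(result.restart_elbos.max())

    def test_constant_single_unit_counts_leave_feature_unused(self):
        T = 60
        table = ObservationTable(
            np.arange(T), np.zeros(T, int), np.full(T, 4), T, 1
        )
        config = ModelConfig(n_features=1, n_restarts=2, max_iter=60, seed=0)
        result = st.fit(table, config=config)
        summ = result.feature_summary
        assert not summ["used"].iloc[0]
        assert abs(summ["population_gain"].iloc[0] - 1.0) < 0.05

    def test_permutation_equivariance(self):
        # relabeling the tags of the initialization (and sweeping them in the
        # relabeled order) relabels the whole fitted trajectory
        rng = np.random.default_rng(16)
        data = make_data(rng, U=3, T=40, rate=2.0)
        config = ModelConfig(n_features=3, overdispersion=False, seed=0)
        perm = [2, 0, 1]  # s_b chain k := s_a chain perm[k]
        inv = [perm.index(j) for j in range(3)]
        s_a = init_state(data, config, np.random.default_rng(4))
        s_b = copy.deepcopy(s_a)
        s_b.chain_posteriors = [s_a.chain_posteriors[j] for j in perm]
        s_b.chain_evidences = [s_a.chain_evidences[j] for j in perm]
        s_b.f_factors = s_b.f_factors[perm].copy()
        s_b.chain_posteriors = copy.deepcopy(s_b.chain_posteriors)
        for _ in range(25):
            sweep(s_a, data, config)
            sweep(s_b, data, config, chain_order=inv)
        np.testing.assert_allclose(s_a.alpha_z[:, perm], s_b.alpha_z, rtol=1e-12)
        np.testing.assert_allclose(s_a.beta_z[:, perm], s_b.beta_z, rtol=1e-12)
        np.testing.assert_allclose(s_a.cz[perm], s_b.cz, rtol=1e-12)
        for k in range(3):
            np.testing.assert_allclose(
                s_a.chain_posteriors[perm[k]].xi,
                s_b.chain_posteriors[k].xi,
                atol=1e-12,
            )
        np.testing.assert_allclose(s_a.alpha0, s_b.alpha0, rtol=1e-12)
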