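"""Moment summaries, the stochastic-simulator likelihood, MCMC and MAP."""

import numpy as np
import pytest
from scipy.stats import kstest

from cgabm.calibration import (CalibrationProblem, MomentSummary,
                               data_moments, leave_one_out_problem,
                               log_likelihood, log_posterior,
                               map_estimate_from_samples, model_moments,
                               run_mcmc)
from cgabm.params import (DEFAULT_THETA, PRIOR_BOUNDS, SimulationConfig,
                          THETA_NAMES, theta_array)
from cgabm.simulator import ScenarioSpec, Trajectory


def _traj(times, live, dead):
    return Trajectory(times=np.asarray(times, float),
                      live_confluence=np.asarray(live, float),
                      dead_confluence=np.asarray(dead, float))


def _summary(times, mu_live, sd_live=0.0, mu_dead=None, sd_dead=0.0):
    times = np.asarray(times, float)
    mu_live = np.broadcast_to(np.asarray(mu_live, float), times.shape)
    mu_dead = mu_live if mu_dead is None else \
        np.broadcast_to(np.asarray(mu_dead, float), times.shape)
    return MomentSummary(
        mu={"live": mu_live.copy(), "dead": mu_dead.copy()},
        sd={"live": np.full(times.shape, sd_live),
            "dead": np.full(times.shape, sd_dead)},
        n_replicates=4, times=times)


class TestDataMoments:
    def test_mean_and_sample_std(self):
        t = [0.0, 3.0]
        reps = [_traj(t, [v, v], [0.0, 0.0]) for v in (0.1, 0.2, 0.3, 0.4)]
        mm = data_moments(reps)
        assert mm.mu["live"][0] == pytest.approx(0.25)
        assert mm.sd["live"][0] == pytest.approx(0.12909944, rel=1e-6)
        assert mm.n_replicates == 4

    def test_identical_replicates_zero_spread(self):
        reps = [_traj([0, 3], [0.5, 0.6], [0.1, 0.1])] * 3
        mm = data_moments(reps)
        assert np.all(mm.sd["live"] == 0.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            data_moments([_traj([0, 3], [0.5, 0.6], [0.1, 0.1])])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            data_moments([_traj([0, 3], [0.5, 0.6], [0.1, 0.1]),
                          _traj([0, 6], [0.5, 0.6], [0.1, 0.1])])


class TestLogLikelihood:
    def test_single_term_value(self):
        """One time point, one output, unit sigma, unit residual."""
        t = [0.0]
        model = _summary(t, 1.0, sd_live=1.0)
        data = _summary(t, 0.0, sd_live=0.0)
        ll = log_likelihood(model, data, {"live": 1.0, "dead": 0.0})
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi) - 0.5, rel=1e-9)
        assert ll == pytest.approx(-1.41894, abs=1e-5)

    def test_maximized_when_means_agree(self):
        t = np.arange(5.0)
        data = _summary(t, 0.5, sd_live=0.05, sd_dead=0.05)
        best = log_likelihood(_summary(t, 0.5, sd_live=0.02, sd_dead=0.02), data)
        worse = log_likelihood(_summary(t, 0.55, sd_live=0.02, sd_dead=0.02), data)
        worst = log_likelihood(_summary(t, 0.7, sd_live=0.02, sd_dead=0.02), data)
        assert best > worse > worst

    def test_sign_convention_shifts_by_constant(self):
        t = np.arange(7.0)
        model = _summary(t, 0.4, sd_live=0.03, sd_dead=0.03)
        data = _summary(t, 0.5, sd_live=0.02, sd_dead=0.02)
        minus = log_likelihood(model, data, half_log_2pi_sign=-1)
        plus = log_likelihood(model, data, half_log_2pi_sign=+1)
        n_terms = t.size * 2  # both outputs
        assert plus - minus == pytest.approx(n_terms * np.log(2 * np.pi))

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            log_likelihood(_summary([0.0], 0.5), _summary([3.0], 0.5))

    def test_sigma_floor_keeps_value_finite(self):
        t = [0.0]
        ll = log_likelihood(_summary(t, 0.5), _summary(t, 0.4))
        assert np.isfinite(ll)


@pytest.fixture(scope="module")
def tiny_problem():
    """Three fast scenarios with synthetic data from the simulator itself."""
    cfg = SimulationConfig(m=16, mesh_target_elements=100)
    scenarios = []
    rng = np.random.default_rng(0)
    for i, g in enumerate((0.2, 0.5, 1.0)):
        sc = ScenarioSpec(f"s{g}", glucose0=g, seeding_density=5e4,
                          init_live_confluence=0.4, init_dead_confluence=0.05,
                          well_radius=300.0, horizon=12.0, sample_interval=6.0)
        reps = [model_moments(DEFAULT_THETA, sc, 2, cfg,
                              seeds=np.array([10 * i + j, 10 * i + j + 5]))
                for j in range(1)]
        # build data replicates directly from single runs
        from cgabm.simulator import run as sim_run

        data = data_moments([sim_run(sc, cfg, 100 * i + j)
                             for j in range(3)])
        scenarios.append((sc, data))
    return CalibrationProblem(scenarios=scenarios, config=cfg, N_r=2, seed=4)


class TestLogPosterior:
    def test_outside_prior_is_minus_inf(self, tiny_problem):
        theta = theta_array(DEFAULT_THETA)
        theta[0] = 1.5  # alpha_P_bar beyond its U(0,1) prior
        assert log_posterior(theta, tiny_problem) == -np.inf

    def test_additive_over_scenarios_and_leave_one_out(self, tiny_problem):
        theta = theta_array(DEFAULT_THETA)
        full = log_posterior(theta, tiny_problem)
        parts = []
        for sc, data in tiny_problem.scenarios:
            sub = CalibrationProblem(scenarios=[(sc, data)],
                                     config=tiny_problem.config,
                                     N_r=tiny_problem.N_r,
                                     seed=tiny_problem.seed)
            parts.append(log_posterior(theta, sub))
        assert full == pytest.approx(sum(parts), rel=1e-9)
        held = tiny_problem.scenarios[1][0].name
        loo = leave_one_out_problem(tiny_problem, held)
        assert log_posterior(theta, loo) == pytest.approx(full - parts[1],
                                                          rel=1e-9)

    def test_deterministic_under_common_random_numbers(self, tiny_problem):
        theta = theta_array(DEFAULT_THETA)
        assert log_posterior(theta, tiny_problem) == \
            log_posterior(theta, tiny_problem)


class TestModelMoments:
    def test_same_seeds_identical(self, small_scenario, small_config):
        seeds = np.array([3, 4, 5])
        m1 = model_moments(DEFAULT_THETA, small_scenario, 3, small_config,
                           seeds=seeds)
        m2 = model_moments(DEFAULT_THETA, small_scenario, 3, small_config,
                           seeds=seeds)
        np.testing.assert_array_equal(m1.mu["live"], m2.mu["live"])
        np.testing.assert_array_equal(m1.sd["dead"], m2.sd["dead"])

    def test_requires_two_replicates(self, small_scenario, small_config):
        with pytest.raises(ValueError):
            model_moments(DEFAULT_THETA, small_scenario, 1, small_config)


def _bounds_problem():
    prob = CalibrationProblem.__new__(CalibrationProblem)
    prob.bounds = {n: PRIOR_BOUNDS[n] for n in THETA_NAMES}
    return prob


class TestMCMC:
    def test_gaussian_target_recovery(self):
        """Posterior mean and spread of a known 5D Gaussian are recovered."""
        lo = np.array([PRIOR_BOUNDS[n][0] for n in THETA_NAMES])
        hi = np.array([PRIOR_BOUNDS[n][1] for n in THETA_NAMES])
        mu = lo + 0.4 * (hi - lo)
        sd = 0.06 * (hi - lo)

        def lp(th):
            th = np.asarray(th)
            if np.any(th < lo) or np.any(th > hi):
                return -np.inf
            return float(-0.5 * np.sum(((th - mu) / sd) ** 2))

        post = run_mcmc(_bounds_problem(), n_chains=12, n_steps=1500, rng=2,
                        log_prob=lp)
        flat = post.pooled()
        assert flat.shape[0] >= 8000
        for j in range(5):
            se = sd[j] / np.sqrt(200.0)  # generous effective sample size
            assert abs(flat[:, j].mean() - mu[j]) < 4 * se
            assert flat[:, j].std() == pytest.approx(sd[j], rel=0.15)
        assert all(r < 1.2 for r in post.r_hat.values())

    def test_flat_likelihood_samples_prior(self):
        lo = np.array([PRIOR_BOUNDS[n][0] for n in THETA_NAMES])
        hi = np.array([PRIOR_BOUNDS[n][1] for n in THETA_NAMES])

        def lp(th):
            th = np.asarray(th)
            return 0.0 if np.all((th >= lo) & (th <= hi)) else -np.inf

        post = run_mcmc(_bounds_problem(), n_chains=12, n_steps=1500, rng=8,
                        log_prob=lp)
        flat = post.pooled()
        # thin to soften autocorrelation, then KS against the uniform
        for j in (0, 4):
            u = (flat[::37, j] - lo[j]) / (hi[j] - lo[j])
            assert kstest(u, "uniform").pvalue > 0.01

    def test_seeded_chains_identical(self):
        def lp(th):
            th = np.asarray(th)
            if np.any(th < 0) or np.any(th > 1):
                return -np.inf
            return float(-0.5 * np.sum((th - 0.4) ** 2 / 0.01))

        prob = _bounds_problem()
        prob.bounds = {n: (0.0, 1.0) for n in THETA_NAMES}
        p1 = run_mcmc(prob, n_chains=10, n_steps=200, rng=6, log_prob=lp)
        p2 = run_mcmc(prob, n_chains=10, n_steps=200, rng=6, log_prob=lp)
        np.testing.assert_array_equal(p1.samples, p2.samples)


class TestMAP:
    def test_gaussian_samples_mode_near_mean(self, rng):
        mu = np.array([0.3, 0.01, 0.2, 0.02, 0.1])
        sd = np.array([0.05, 0.002, 0.04, 0.004, 0.02])
        samples = mu + sd * rng.standard_normal((4000, 5))
        est, bw = map_estimate_from_samples(samples)
        assert bw > 0
        for j in range(5):
            assert abs(est[j] - mu[j]) < 1.5 * sd[j]

    def test_degenerate_point_mass(self):
        samples = np.tile([0.1, 0.2, 0.3, 0.4, 0.5], (200, 1))
        est, bw = map_estimate_from_samples(samples)
        np.testing.assert_allclose(est, [0.1, 0.2, 0.3, 0.4, 0.5])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            map_estimate_from_samples(np.zeros((10, 5)))
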