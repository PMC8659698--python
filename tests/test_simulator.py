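"""Hybrid simulation loop, observables and coarse-graining behaviour."""

from dataclasses import replace

import numpy as np
import pytest

from cgabm.microenvironment import build_disc_mesh
from cgabm.params import SimulationConfig, DEFAULT_THETA, THETA_NAMES
from cgabm.population import DEAD, P_PRE, Q
from cgabm.simulator import (ScenarioSpec, coarse_grain_geometry, confluence,
                             initialize, resolution_error, run, tumor_radius)

from conftest import make_population


class TestCoarseGrainGeometry:
    def test_identity_at_m_one(self):
        assert coarse_grain_geometry((9.953, 5.295, 12.083), 1) == \
            pytest.approx((9.953, 5.295, 12.083))

    def test_hundred_cells_scale_ten(self):
        r, rn, ra = coarse_grain_geometry((9.953, 5.295, 12.083), 100)
        assert r == pytest.approx(99.53)
        assert rn == pytest.approx(52.95)
        assert ra == pytest.approx(120.83)

    def test_total_area_preserved(self):
        """N/m agents of sqrt(m)-scaled radius cover the same total area."""
        n, m, r0 = 600, 100, 9.953
        r, _, _ = coarse_grain_geometry((r0, 5.3, 12.1), m)
        assert (n / m) * np.pi * r**2 == pytest.approx(n * np.pi * r0**2)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            coarse_grain_geometry((9.953, 5.295, 12.083), 0)


class TestInitialize:
    def test_uniform_field_at_scenario_glucose(self, small_scenario,
                                               small_config, rng):
        sc = replace(small_scenario, glucose0=0.2)
        pop, field = initialize(sc, small_config, rng)
        assert np.all(field.sigma == 0.2)

    def test_empty_scenario(self, small_config, rng):
        sc = ScenarioSpec("empty", 0.5, 0.0, 0.0, 0.0, well_radius=400.0)
        pop, _ = initialize(sc, small_config, rng)
        assert len(pop) == 0
        tr = run(sc, small_config, 0)
        assert np.all(tr.live_confluence == 0.0)
        assert np.all(tr.dead_confluence == 0.0)

    def test_requested_confluence_within_one_agent(self, small_scenario,
                                                   small_config, rng):
        pop, _ = initialize(small_scenario, small_config, rng)
        live, dead = confluence(pop, small_scenario.well_radius)
        agent_frac = (small_config.m * np.pi * small_config.cell_radius**2
                      / (np.pi * small_scenario.well_radius**2))
        assert abs(live - small_scenario.init_live_confluence) <= agent_frac
        assert abs(dead - small_scenario.init_dead_confluence) <= agent_frac

    def test_all_quiescent_switch(self, small_scenario, rng):
        cfg = SimulationConfig(m=16, mesh_target_elements=120,
                               all_quiescent_init=True)
        pop, _ = initialize(small_scenario, cfg, rng)
        assert not np.any(pop.phenotype == P_PRE)

    def test_proliferative_fraction_follows_intensity(self, small_scenario,
                                                      small_config, rng):
        pop, _ = initialize(small_scenario, small_config, rng)
        live = pop.phenotype != DEAD
        sH = DEFAULT_THETA["sigma_H"]
        expected = DEFAULT_THETA["alpha_P_bar"] * \
            (small_scenario.glucose0 - sH) / (1 - sH)
        frac = np.mean(pop.phenotype[live] == P_PRE)
        assert frac == pytest.approx(expected, abs=1.5 / live.sum())


class TestConfluence:
    def test_area_ratio(self):
        pop = make_population(np.zeros((100, 2)), radius=10.0)
        live, dead = confluence(pop, 1000.0)
        assert live == pytest.approx(0.01)
        assert dead == 0.0

    def test_overlap_counted_twice(self):
        pop = make_population([[0.0, 0.0], [0.0, 0.0]], radius=10.0)
        live, _ = confluence(pop, 100.0)
        assert live == pytest.approx(2 * 100.0 / 100.0**2)

    def test_empty(self):
        pop = make_population(np.empty((0, 2)))
        assert confluence(pop, 100.0) == (0.0, 0.0)


class TestTumorRadius:
    def test_single_agent(self):
        pop = make_population([[5.0, -3.0]], radius=10.0)
        assert tumor_radius(pop) == pytest.approx(10.0)

    def test_translation_invariant(self, rng):
        x = rng.uniform(-100, 100, (50, 2))
        p1 = make_population(x)
        p2 = make_population(x + [1234.0, -567.0])
        assert tumor_radius(p1) == pytest.approx(tumor_radius(p2))

    def test_uniform_disc_order_statistic(self, rng):
        n = 10000
        r = 500.0 * np.sqrt(rng.random(n))
        t = rng.uniform(0, 2 * np.pi, n)
        pop = make_population(np.column_stack([r * np.cos(t), r * np.sin(t)]),
                              radius=5.0)
        expected = 500.0 * np.sqrt(0.95) + 5.0
        assert tumor_radius(pop) == pytest.approx(expected, rel=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tumor_radius(make_population(np.empty((0, 2))))


class TestRun:
    def test_sampling_grid(self, small_scenario, small_config):
        sc = replace(small_scenario, horizon=96.0, sample_interval=3.0)
        tr = run(sc, small_config, 3)
        assert tr.times.size == 33
        assert np.all(np.diff(tr.times) == 3.0)

    def test_deterministic_for_fixed_seed(self, small_scenario, small_config):
        t1 = run(small_scenario, small_config, 11)
        t2 = run(small_scenario, small_config, 11)
        np.testing.assert_array_equal(t1.live_confluence, t2.live_confluence)
        np.testing.assert_array_equal(t1.dead_confluence, t2.dead_confluence)

    def test_dead_constant_without_death_channel(self, small_scenario):
        theta = dict(SimulationConfig().theta)
        theta["alpha_D_bar"] = 0.0
        theta["gamma_D"] = 0.0
        cfg = SimulationConfig(theta=theta, m=16, mesh_target_elements=120)
        tr = run(small_scenario, cfg, 5)
        np.testing.assert_allclose(tr.dead_confluence, tr.dead_confluence[0])

    def test_dead_confluence_monotone(self, small_scenario, small_config):
        tr = run(small_scenario, small_config, 7)
        assert np.all(np.diff(tr.dead_confluence) >= -1e-12)

    def test_no_divisions_below_glucose_threshold(self, small_scenario):
        """With initial glucose at or below the threshold the proliferation
        intensity is identically zero, so live confluence never grows."""
        theta = dict(SimulationConfig().theta)
        theta["sigma_H"] = 0.6
        cfg = SimulationConfig(theta=theta, m=16, mesh_target_elements=120)
        sc = replace(small_scenario, glucose0=0.5)
        tr = run(sc, cfg, 9)
        assert np.all(tr.live_confluence <= tr.live_confluence[0] + 1e-12)

    def test_parameter_sweep_directionality(self, small_scenario):
        """Mean final confluences move with each parameter as the one-at-a-
        time sweep reports: live rises with the proliferation rate and falls
        with the death/starvation parameters (dead moves oppositely)."""
        n_pairs = 6
        sc = replace(small_scenario, glucose0=0.2, horizon=72.0,
                     init_live_confluence=0.5, init_dead_confluence=0.3)

        def mean_final(theta):
            cfg = SimulationConfig(theta=theta, m=16, mesh_target_elements=120)
            L, Dd = [], []
            for s in range(n_pairs):
                tr = run(sc, cfg, 100 + s)
                L.append(tr.live_confluence[-1])
                Dd.append(tr.dead_confluence[-1])
            return np.mean(L), np.mean(Dd)

        base = {n: DEFAULT_THETA[n] for n in THETA_NAMES}
        # exaggerated one-at-a-time changes keep the check cheap but clear
        perturb = {"alpha_P_bar": 4.0, "alpha_D_bar": 40.0, "lambda": 8.0,
                   "gamma_D": 8.0, "sigma_H": 6.0}
        L0, D0 = mean_final(base)
        for name, factor in perturb.items():
            theta = dict(base)
            theta[name] = min(theta[name] * factor, 1.0)
            L1, D1 = mean_final(theta)
            if name == "alpha_P_bar":
                assert L1 > L0
            else:
                assert L1 < L0, name
                assert D1 > D0, name


class TestResolutionError:
    def test_identity_at_m_one(self, small_scenario, small_config):
        out = resolution_error(small_scenario, small_config, [1], n_reps=2,
                               rng=3, record_radius=False)
        assert out[1]["live"]["mean"] == 0.0
        assert out[1]["dead"]["mean"] == 0.0

    def test_reference_required(self, small_scenario, small_config):
        with pytest.raises(ValueError):
            resolution_error(small_scenario, small_config, [16], n_reps=2)
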