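"""Photokinetic-swimmer simulator: dynamics, statistics, and the 1/v law."""

import numpy as np
import pytest

from photokin.agent_sim import (
    SimConfig,
    density_histogram,
    init_population,
    run_to_stationary,
    sample_schultz,
    step,
)
from photokin.light_response import IntensityResponse, MemoryParams, step_response


def small_cfg(**kw):
    base = dict(
        box=(200.0, 200.0), dt=0.05, n_agents=2000, alpha_motile=1.0,
        mean_sat_speed=8.0, Z=3.0, seed=7,
    )
    base.update(kw)
    return SimConfig(**base)


def uniform_light(level=255.0, shape=(100, 100)):
    return np.full(shape, level)


class TestInitPopulation:
    def test_all_motile_when_alpha_one(self, resp):
        pop = init_population(small_cfg(alpha_motile=1.0), resp)
        assert pop.motile.all()

    def test_saturation_speed_mean_within_se(self, resp):
        cfg = small_cfg(n_agents=50_000)
        pop = init_population(cfg, resp)
        se = cfg.mean_sat_speed / np.sqrt((cfg.Z + 1) * cfg.n_agents)
        assert abs(pop.v_sat.mean() - cfg.mean_sat_speed) < 4 * se

    def test_fixed_seed_bit_identical(self, resp):
        a = init_population(small_cfg(), resp)
        b = init_population(small_cfg(), resp)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.v_sat, b.v_sat)

    def test_memory_adapted_to_initial_light(self, resp):
        light = uniform_light(50.0)
        pop = init_population(small_cfg(), resp, light)
        assert pop.m == pytest.approx(pop.v_sat * resp.f(50.0))

    def test_schultz_sampler_moments(self, rng):
        s = sample_schultz(rng, 6.0, 2.0, 100_000)
        assert s.mean() == pytest.approx(6.0, rel=0.02)
        assert s.var() == pytest.approx(36.0 / 3.0, rel=0.05)

    def test_invalid_config_named(self, resp):
        with pytest.raises(ValueError, match="light pixel"):
            init_population(small_cfg(dt=0.5), resp)
        with pytest.raises(ValueError, match="alpha_motile"):
            init_population(small_cfg(alpha_motile=1.2, dt=0.05), resp)


class TestStep:
    def test_memoryless_speed_is_commanded_speed(self, resp):
        cfg = small_cfg(mem=None)
        light = uniform_light(150.0)
        pop = init_population(cfg, resp, light)
        step(pop, light, resp, cfg)
        mot = pop.motile
        assert pop.speed[mot] == pytest.approx(pop.v_sat[mot] * resp.f(150.0))

    def test_straight_line_motion_without_rotational_noise(self, resp):
        cfg = small_cfg(tau_rot=1e12, n_agents=50, D_brownian=0.0)
        light = uniform_light()
        pop = init_population(cfg, resp, light)
        th0 = pop.theta.copy()
        x0, y0 = pop.x.copy(), pop.y.copy()
        for _ in range(100):
            step(pop, light, resp, cfg)
        assert pop.theta == pytest.approx(th0, abs=1e-5)
        # displacement direction matches the heading (minimum-image unwrap)
        L = cfg.box[0]
        dx = (pop.x - x0 + L / 2) % L - L / 2
        dy = (pop.y - y0 + L / 2) % L - L / 2
        ok = np.hypot(dx, dy) > 1e-6
        dang = (np.arctan2(dy, dx) - th0 + np.pi) % (2 * np.pi) - np.pi
        assert np.abs(dang[ok]).max() < 1e-4

    def test_positions_stay_inside_box(self, resp):
        for boundary in ("periodic", "reflecting"):
            cfg = small_cfg(boundary=boundary, n_agents=500)
            light = uniform_light()
            pop = init_population(cfg, resp, light)
            for _ in range(200):
                step(pop, light, resp, cfg)
            assert pop.x.min() >= 0 and pop.x.max() <= cfg.box[0]
            assert pop.y.min() >= 0 and pop.y.max() <= cfg.box[1]

    def test_tumbling_randomizes_heading(self, resp):
        cfg = small_cfg(tau_run=1.0, tau_rot=1e9, n_agents=3000, D_brownian=0.0)
        light = uniform_light()
        pop = init_population(cfg, resp, light)
        th0 = pop.theta.copy()
        for _ in range(100):  # 5 s >> tau_run: nearly every agent tumbled
            step(pop, light, resp, cfg)
        assert (pop.theta != th0).mean() > 0.95

    def test_population_mean_speed_follows_step_response(self, resp, mem):
        # switch uniform illumination and compare the ensemble-average speed
        # with the two-timescale response curve
        cfg = small_cfg(n_agents=20_000, mem=mem, dt=0.07)
        light1, light2 = uniform_light(17.0), uniform_light(150.0)
        pop = init_population(cfg, resp, light1)
        V1 = cfg.mean_sat_speed * resp.f(17.0)
        V2 = cfg.mean_sat_speed * resp.f(150.0)
        checks = {5.0: None, 35.0: None, 105.0: None}
        t = 0.0
        for _ in range(int(110.0 / cfg.dt)):
            step(pop, light2, resp, cfg)
            t += cfg.dt
            for tc in checks:
                if checks[tc] is None and t >= tc:
                    checks[tc] = pop.speed[pop.motile].mean()
        for tc, measured in checks.items():
            expected = step_response(tc, V1, V2, mem)
            assert measured == pytest.approx(expected, rel=0.02)


class TestRunToStationary:
    def test_agent_count_conserved_every_snapshot(self, resp):
        cfg = small_cfg(n_agents=300)
        light = uniform_light()
        pop = init_population(cfg, resp, light)
        snaps = run_to_stationary(pop, light, resp, cfg, 20.0, 5.0, 2.0)
        assert snaps.shape[1] == 300
        assert np.isfinite(snaps).all()

    def test_uniform_light_gives_flat_density(self, resp):
        cfg = small_cfg(n_agents=20_000, alpha_motile=1.0)
        light = uniform_light()
        pop = init_population(cfg, resp, light)
        snaps = run_to_stationary(pop, light, resp, cfg, 60.0, 20.0, 5.0)
        rho = density_histogram(snaps, (10, 10), cfg.box)
        # counting noise: ~200 agents/bin * 8 snapshots, correlated between
        # snapshots; flat to a few percent
        assert rho.std() < 0.05
        assert rho.mean() == pytest.approx(1.0)

    def test_inverse_speed_law_two_levels(self, resp):
        # instantaneous response: density ratio equals inverse speed ratio
        light = np.where(np.arange(100) < 50, 16.667, 250.0)[None, :] * np.ones(
            (100, 1)
        )
        cfg = small_cfg(n_agents=8000, dt=0.07, seed=3)
        pop = init_population(cfg, resp, light)
        snaps = run_to_stationary(pop, light, resp, cfg, 300.0, 120.0, 4.0)
        rho = density_histogram(snaps, (1, 2), cfg.box)
        v_ratio = resp.mean_speed(250.0) / resp.mean_speed(16.667)
        assert rho[0, 0] / rho[0, 1] == pytest.approx(v_ratio, rel=0.05)

    def test_fixed_seed_bit_identical_trajectories(self, resp):
        light = uniform_light()

        def run():
            cfg = small_cfg(n_agents=200)
            pop = init_population(cfg, resp, light)
            return run_to_stationary(pop, light, resp, cfg, 10.0, 2.0, 1.0)

        assert np.array_equal(run(), run())


class TestEffectiveDiffusion:
    def test_msd_matches_rotational_diffusion_theory(self, resp):
        # 2-D active particle: MSD(t) = 2 <v^2> tau^2 (t/tau + e^(-t/tau) - 1),
        # giving D_eff = <v^2> tau_rot / 2 at long times
        cfg = small_cfg(n_agents=3000, box=(5000.0, 5000.0), D_brownian=0.0,
                        dt=0.05, tau_rot=20.0)
        light = uniform_light(255.0, (10, 10))
        pop = init_population(cfg, resp, light, pixel_size=500.0)
        x, y = pop.x.copy(), pop.y.copy()
        disp = np.zeros((cfg.n_agents, 2))
        L = cfg.box[0]
        t_end = 100.0
        for _ in range(int(t_end / cfg.dt)):
            step(pop, light, resp, cfg, pixel_size=500.0)
            dx = (pop.x - x + L / 2) % L - L / 2  # minimum-image unwrap
            dy = (pop.y - y + L / 2) % L - L / 2
            disp[:, 0] += dx
            disp[:, 1] += dy
            x, y = pop.x.copy(), pop.y.copy()
        msd = float((disp**2).sum(axis=1).mean())
        v2 = float((pop.v_sat * resp.f(255.0)) ** 2 @ np.ones(cfg.n_agents)) / cfg.n_agents
        tau = cfg.tau_rot
        theory = 2.0 * v2 * tau**2 * (t_end / tau + np.exp(-t_end / tau) - 1.0)
        assert msd == pytest.approx(theory, rel=0.10)


class TestDensityHistogram:
    def test_uniform_positions_near_one(self, rng):
        pos = rng.uniform(0, 100, (200_000, 2))
        rho = density_histogram(pos, (5, 5), (100.0, 100.0))
        assert rho == pytest.approx(1.0, abs=0.05)

    def test_single_occupied_bin(self):
        pos = np.full((50, 2), 5.0)
        rho = density_histogram(pos, (4, 4), (100.0, 100.0))
        assert rho.max() == 16.0
        assert rho.sum() == 16.0

    def test_mean_is_exactly_one(self, rng):
        pos = rng.uniform(0, 50, (1000, 2))
        assert density_histogram(pos, (8, 8), (50.0, 50.0)).mean() == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            density_histogram(np.empty((0, 2)), (4, 4), (10.0, 10.0))
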