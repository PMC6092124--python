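"""End-to-end in-silico protocols tying the generator and the analyses together.

Each function reproduces one of the study's measurement protocols on
synthetic data at a fixed seed and returns the measured quantities:

* `step_response_recovery` — square-wave illumination, two-timescale fit.
* `chessboard_intercept` — multi-level chessboard, level-averaged density
  versus inverse speed, straight-line fit of the high-speed branch.
* `two_level_ratio` — 2:1 speed-contrast map, baseline-subtracted
  modulation ratio of the responsive component.
* `memory_consistency` — fine stripes with memory on; compares the
  stationary density to the blurred and unblurred predictions.
* `closed_loop_experiment` — proportional feedback versus open loop on a
  two-level target, plus morphing to the complementary target.
* `ddm_recovery` — bright-field rendering of a uniform run and DDM
  parameter recovery.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from . import agent_sim, ddm, feedback, imaging, memory_blur, patterns
from .agent_sim import SimConfig, density_histogram, init_population
from .feedback import FeedbackConfig
from .light_response import (
    IntensityResponse,
    MemoryParams,
    fit_step_response,
    square_wave_response,
)

__all__ = [
    "step_response_recovery",
    "chessboard_intercept",
    "two_level_ratio",
    "memory_consistency",
    "closed_loop_experiment",
    "ddm_recovery",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds (< 2**31) spawned from one master seed."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def step_response_recovery(
    seed: int,
    V1: float = 4.0,
    V2: float = 8.0,
    beta: float = 0.44,
    tau_m: float = 35.0,
    period: float = 200.0,
    n_periods: int = 8,
    dt_sample: float = 1.0,
    noise_frac: float = 0.02,
):
    """Generate the square-wave speed trace and refit the two-timescale model.

    1 s sampling over ``n_periods`` periods of the square wave, Gaussian
    noise of ``noise_frac`` times the mean speed, periodic-steady-state fit
    with a shared relaxation time for rising and falling branches.
    """
    rng = np.random.default_rng(seed)
    mem = MemoryParams(beta=beta, tau_m=tau_m)
    times = np.arange(0.0, n_periods * period, dt_sample)
    trace = square_wave_response(times, V1, V2, mem, period)
    noisy = trace + noise_frac * trace.mean() * rng.standard_normal(times.size)
    fit = fit_step_response(times, noisy, period=period)
    return {"fit": fit, "times": times, "speeds": noisy, "true": mem}


def chessboard_intercept(
    seed: int,
    resp: IntensityResponse | None = None,
    n_agents: int = 20_000,
    alpha_motile: float = 0.5,
    tile_px: int = 20,
    t_total: float = 900.0,
    t_burn: float = 300.0,
    sample_every: float = 5.0,
    n_high: int | None = None,
    pixel_size: float = 2.0,
):
    """12-level chessboard without memory: intercept of density vs inverse speed.

    The fitted intercept estimates the non-responsive fraction ``1 - alpha``.
    Without memory every level lies on the line, so the default fits all 12
    levels: the slow levels anchor the regression and suppress the large
    extrapolation leverage a high-speed-only fit would have.  Restrict with
    ``n_high`` when analysing memory-blurred data, where the low-speed
    branch bends away from the line.
    """
    resp = resp or IntensityResponse()
    intensity, labels = patterns.chessboard(
        n_tiles=(12, 12), tile_px=tile_px, levels=np.linspace(0.0, 255.0, 12)
    )
    box = (intensity.shape[1] * pixel_size, intensity.shape[0] * pixel_size)
    cfg = SimConfig(
        box=box, dt=0.07, n_agents=n_agents, alpha_motile=alpha_motile,
        mem=None, seed=seed,
    )
    pop = init_population(cfg, resp, intensity, pixel_size)
    snaps = agent_sim.run_to_stationary(
        pop, intensity, resp, cfg, t_total, t_burn, sample_every, pixel_size
    )
    rho = density_histogram(snaps, intensity.shape, box)
    speed = resp.mean_speed(intensity)
    table = memory_blur.density_vs_inverse_speed(rho, speed, labels)
    fit = memory_blur.fit_density_line(table, n_high=n_high)
    return {"table": table, "fit": fit, "intercept": fit.intercept, "slope": fit.slope}


def two_level_ratio(
    seed: int,
    resp: IntensityResponse | None = None,
    n_agents: int = 20_000,
    alpha_motile: float = 0.5,
    v_pair: tuple[float, float] = (3.5, 7.0),
    t_total: float = 900.0,
    t_burn: float = 300.0,
    sample_every: float = 5.0,
    pixel_size: float = 2.0,
):
    """Two-level map with 2:1 mean-speed contrast: modulation ratio of the motile part.

    The two intensity bands are chosen so the population-mean speeds are
    ``v_pair`` (ratio 2 by default).  The non-responsive baseline ``q`` is the
    intercept of the two-point line in the (1/v, density) plane, and the
    reported ratio is ``max(rho* - q) / min(rho* - q)`` over the two levels.
    """
    resp = resp or IntensityResponse()
    I_lo, I_hi = (float(resp.invert(v)) for v in v_pair)
    intensity, labels = patterns.two_level_stripes((240, 240), I_lo, I_hi)
    box = (intensity.shape[1] * pixel_size, intensity.shape[0] * pixel_size)
    cfg = SimConfig(
        box=box, dt=0.07, n_agents=n_agents, alpha_motile=alpha_motile,
        mem=None, seed=seed,
    )
    pop = init_population(cfg, resp, intensity, pixel_size)
    snaps = agent_sim.run_to_stationary(
        pop, intensity, resp, cfg, t_total, t_burn, sample_every, pixel_size
    )
    rho = density_histogram(snaps, intensity.shape, box)
    speed = resp.mean_speed(intensity)
    table = memory_blur.density_vs_inverse_speed(rho, speed, labels)
    fit = memory_blur.fit_density_line(table)
    q = fit.intercept
    resid = table["mean_density"].to_numpy() - q
    ratio = float(resid.max() / resid.min())
    return {"table": table, "baseline": q, "ratio": ratio}


def memory_consistency(
    seed: int,
    resp: IntensityResponse | None = None,
    mem: MemoryParams | None = None,
    n_agents: int = 15_000,
    v0: float = 5.0,
    rel_amplitude: float = 0.1,
    wavelength_um: float = 128.0,
    t_total: float = 900.0,
    t_burn: float = 200.0,
    sample_every: float = 2.0,
    pixel_size: float = 2.0,
):
    """Fine cosine stripes with memory on: blurred vs unblurred density prediction.

    All agents respond (alpha = 1) and the speed modulation is weak (10%
    around ``v0``), the regime where the Fourier-space blur is derived.
    Returns the L2 errors of the simulated stationary density profile
    against the blurred and the unblurred predictions.
    """
    resp = resp or IntensityResponse()
    mem = mem or MemoryParams()
    nx = int(round(4 * wavelength_um / pixel_size))  # four stripes along x
    ny = nx // 4
    x = (np.arange(nx) + 0.5) * pixel_size
    v_des = v0 * (1.0 + rel_amplitude * np.cos(2.0 * np.pi * x / wavelength_um))
    intensity = np.tile(resp.invert(v_des), (ny, 1))
    box = (nx * pixel_size, ny * pixel_size)
    cfg = SimConfig(
        box=box, dt=0.07, n_agents=n_agents, alpha_motile=1.0,
        mem=mem, seed=seed,
    )
    pop = init_population(cfg, resp, intensity, pixel_size)
    snaps = agent_sim.run_to_stationary(
        pop, intensity, resp, cfg, t_total, t_burn, sample_every, pixel_size
    )
    rho = density_histogram(snaps, intensity.shape, box)

    V = resp.mean_speed(intensity)
    w = memory_blur.blur_speed_map(
        V, mem.beta, tau_m=mem.tau_m, pixel_size=pixel_size
    )
    pred_blur = memory_blur.predict_density(w, alpha=1.0)
    pred_plain = memory_blur.predict_density(V, alpha=1.0)

    prof_sim = rho.mean(axis=0)
    prof_blur = pred_blur.mean(axis=0)
    prof_plain = pred_plain.mean(axis=0)
    l2_blur = float(np.linalg.norm(prof_sim - prof_blur))
    l2_plain = float(np.linalg.norm(prof_sim - prof_plain))
    return {
        "l2_blurred": l2_blur,
        "l2_unblurred": l2_plain,
        "profile_sim": prof_sim,
        "profile_blurred": prof_blur,
        "profile_unblurred": prof_plain,
    }


def closed_loop_experiment(
    seed: int,
    resp: IntensityResponse | None = None,
    mem: MemoryParams | None = None,
    n_agents: int = 8_000,
    grid: int = 64,
    light_pixel_um: float = 4.0,
    target_levels: tuple[float, float] = (0.8, 1.2),
    gain: float = 50.0,
    n_open_iterations: int = 6,
    n_fb_iterations: int = 30,
    morph_iterations: int = 18,
):
    """Feedback vs open loop on a two-level target, then morph to its complement.

    Runs three phases with identically initialized populations: a closed
    loop (warm-up then 30 feedback iterations), an open-loop reference with
    the same naive initial pattern, and a morph continuing the closed loop
    toward the inverted target.  Plateau distances are means over the last
    eight iterations.
    """
    resp = resp or IntensityResponse()
    mem = mem or MemoryParams()
    lo, hi = target_levels
    target, _ = patterns.two_level_stripes((grid, grid), lo, hi)
    box = (grid * light_pixel_um, grid * light_pixel_um)
    s1, s2 = _child_seeds(seed, 2)
    n_total = n_open_iterations + n_fb_iterations
    fb = FeedbackConfig(gain=gain, max_iterations=n_total)

    def make_pop(s):
        cfg = SimConfig(
            box=box, dt=0.1, n_agents=n_agents, alpha_motile=0.5,
            mem=mem, seed=s,
        )
        return cfg, init_population(cfg, resp, None, light_pixel_um)

    pattern0 = feedback.naive_pattern(target, resp, 0.5, fb.bounds)

    cfg_c, pop_c = make_pop(s1)
    closed = feedback.run_closed_loop(
        pop_c, cfg_c, resp, target, fb, pattern0,
        fb_on_after=n_open_iterations * fb.period_s,
    )
    cfg_o, pop_o = make_pop(s2)
    open_ = feedback.run_closed_loop(
        pop_o, cfg_o, resp, target, fb, pattern0, fb_on_after=np.inf
    )
    new_target = (lo + hi) - target  # complementary two-level image
    morph_res = feedback.morph(
        pop_c, cfg_c, resp, closed, new_target, fb, morph_iterations
    )
    return {
        "closed": closed,
        "open": open_,
        "closed_plateau": float(np.mean(closed.dist[-8:])),
        "open_plateau": float(np.mean(open_.dist[-8:])),
        "pattern_naive": pattern0,
        "morph": morph_res,
    }


def ddm_recovery(
    seed: int,
    resp: IntensityResponse | None = None,
    n_agents: int = 10_000,
    alpha_motile: float = 0.6,
    grid: int = 256,
    n_frames: int = 800,
    frame_interval: float = 0.05,
    pixel_size: float = 2.0,
):
    """Bright-field stack of a uniformly lit run, DDM analysis, parameter recovery.

    Returns the band-averaged DDM fit alongside the ground-truth motile-
    population mean speed, speed sd and motile fraction realized in the
    sampled population.
    """
    resp = resp or IntensityResponse()
    s_sim, s_render = _child_seeds(seed, 2)
    box = (grid * pixel_size, grid * pixel_size)
    light = np.full((grid, grid), 255.0)
    cfg = SimConfig(
        box=box, dt=frame_interval, n_agents=n_agents,
        alpha_motile=alpha_motile, mem=None, seed=s_sim, projection_3d=True,
    )
    pop = init_population(cfg, resp, light, pixel_size)
    snaps = agent_sim.run_to_stationary(
        pop, light, resp, cfg,
        t_total=n_frames * frame_interval, t_burn=0.0,
        sample_every=frame_interval, pixel_size=pixel_size,
    )
    render_cfg = imaging.RenderConfig(
        psf_sigma=1.0, counts_per_agent=30.0, gaussian_noise_sd=0.3
    )
    stack = imaging.render_stack(
        snaps, (grid, grid), pixel_size, render_cfg, mode="brightfield",
        rng=np.random.default_rng(s_render),
    )
    curves = ddm.image_structure_function(stack, pixel_size, frame_interval)
    fit = ddm.fit_ddm(curves)
    f = float(resp.f(255.0))
    v_mot = pop.v_sat[pop.motile] * f
    return {
        "fit": fit,
        "curves": curves,
        "true_v": float(v_mot.mean()),
        "true_sigma": float(v_mot.std()),
        "true_alpha": float(pop.motile.mean()),
    }
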