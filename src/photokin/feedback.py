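"""Closed-loop proportional control of the light pattern against a target density.

The controller runs one iteration every ``period_s`` seconds (20 s default):
simulate/observe the density, rescale it onto the target's histogram,
and update the illumination pixelwise,

    I_{n+1}(r) = clip( I_n(r) + P * [rho_s(r) - rho_tar(r)], bounds )

with proportional gain P > 0: where density exceeds the target the light is
increased, speeding bacteria up and depleting the excess.  Because the speed
response is memory-blurred, the converged pattern is a *sharpened* version of
the naive (model-free) pattern — the loop precompensates the blur.

`run_closed_loop` exercises the controller in silico against the agent
simulator, measuring density by time-averaged position histograms (with a
small smoothing), exactly as the rest of the package measures it.  `morph`
swaps the target of a running loop and reports the exponential time constant
of the approach to the new target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit

from . import agent_sim
from .agent_sim import AgentPopulation, SimConfig, density_histogram
from .imaging import distance, percentile_rescale
from .light_response import IntensityResponse

__all__ = [
    "FeedbackConfig",
    "LoopState",
    "MorphResult",
    "update_pattern",
    "naive_pattern",
    "run_closed_loop",
    "morph",
]


@dataclass
class FeedbackConfig:
    """Proportional-control parameters.

    ``gain`` is in intensity units per density unit, sized so the largest
    per-iteration change stays within ~10% of the dynamic range at the
    initial error.  ``bounds`` are the projector limits (8-bit by default)
    and ``quantize`` rounds patterns to integer levels like the hardware.
    """

    gain: float = 50.0
    period_s: float = 20.0
    bounds: tuple[float, float] = (0.0, 255.0)
    quantize: bool = True
    max_iterations: int = 40
    measure_every_s: float = 1.0
    smooth_sigma_px: float = 1.0
    divergence_patience: int = 5

    def __post_init__(self):
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds min must be below max")
        if self.period_s <= 0 or self.measure_every_s <= 0:
            raise ValueError("periods must be positive")


@dataclass
class LoopState:
    """Trajectory of one closed-loop run."""

    pattern: np.ndarray
    target: np.ndarray
    iteration: int = 0
    times: list = field(default_factory=list)
    dist: list = field(default_factory=list)
    fb_active: list = field(default_factory=list)
    densities: list = field(default_factory=list)
    diverged: bool = False

    @property
    def dist_norm(self) -> np.ndarray:
        """Distance history normalized to its initial value."""
        d = np.asarray(self.dist, dtype=float)
        return d / d[0] if d.size else d

    def mean_density(self, last: int = 8) -> np.ndarray:
        """Average of the last ``last`` measured (rescaled-input) density maps."""
        if not self.densities:
            raise ValueError("no densities recorded")
        return np.mean(self.densities[-last:], axis=0)


def update_pattern(
    I_n: np.ndarray,
    rho_s: np.ndarray,
    target: np.ndarray,
    cfg: FeedbackConfig,
) -> np.ndarray:
    """One proportional update, clipped to bounds (and quantized if configured)."""
    I_n = np.asarray(I_n, dtype=float)
    if not (I_n.shape == rho_s.shape == target.shape):
        raise ValueError("pattern, density and target grids must be congruent")
    out = np.clip(I_n + cfg.gain * (rho_s - target), *cfg.bounds)
    if cfg.quantize:
        out = np.rint(out)
    return out


def naive_pattern(
    target: np.ndarray,
    resp: IntensityResponse,
    alpha: float,
    bounds: tuple[float, float] = (0.0, 255.0),
    v_ref: float | None = None,
) -> np.ndarray:
    """Model-free first-guess pattern: invert rho ~ 1/v through the response curve.

    The responsive part of the target, ``target - (1 - alpha)``, is read as
    proportional to the desired inverse speed; the implied speed map is
    scaled to a mean of ``v_ref`` (default 60% of saturation), clipped into
    the invertible range, and pushed through the inverse hyperbola.  No blur
    compensation — that is what the feedback loop is for.
    """
    target = np.asarray(target, dtype=float)
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    u = np.clip(target - (1.0 - alpha), 1e-3, None)
    w = 1.0 / u
    if v_ref is None:
        v_ref = resp.v_dark + 0.6 * (resp.v_sat - resp.v_dark)
    v_des = w * (v_ref / w.mean())
    margin = 0.02 * (resp.v_sat - resp.v_dark)
    v_des = np.clip(v_des, resp.v_dark + margin, resp.v_sat - margin)
    pattern = np.clip(resp.invert(v_des), *bounds)
    return np.rint(pattern)


def _measure(pop, light, resp, sim_cfg, fb, grid_shape, light_px):
    """Simulate one control period, return the smoothed normalized density map."""
    snaps = agent_sim.run_to_stationary(
        pop, light, resp, sim_cfg,
        t_total=fb.period_s, t_burn=0.0, sample_every=fb.measure_every_s,
        pixel_size=light_px,
    )
    rho = density_histogram(snaps, grid_shape, sim_cfg.box)
    if fb.smooth_sigma_px > 0:
        wrap = "wrap" if sim_cfg.boundary == "periodic" else "nearest"
        rho = gaussian_filter(rho, fb.smooth_sigma_px, mode=wrap)
        rho /= rho.mean()
    return rho


def run_closed_loop(
    pop: AgentPopulation,
    sim_cfg: SimConfig,
    resp: IntensityResponse,
    target: np.ndarray,
    fb: FeedbackConfig,
    pattern0: np.ndarray | None = None,
    fb_on_after: float = 0.0,
) -> LoopState:
    """Run the proportional loop in silico against the agent simulator.

    Each iteration simulates ``period_s`` seconds under the current pattern,
    measures the density (position histogram time-averaged over the period,
    lightly smoothed), rescales it onto the target's 10/90 percentiles,
    records the distance, and — once ``t >= fb_on_after`` — applies the
    proportional update.  Set ``fb_on_after = inf`` for an open-loop
    reference run.  A distance growing for several consecutive iterations
    flags divergence with gain-reduction advice.
    """
    target = np.asarray(target, dtype=float)
    if pattern0 is None:
        pattern0 = naive_pattern(target, resp, sim_cfg.alpha_motile, fb.bounds)
    pattern = np.asarray(pattern0, dtype=float).copy()
    if pattern.shape != target.shape:
        raise ValueError("pattern and target grids must be congruent")
    light_px = sim_cfg.box[0] / target.shape[1]
    state = LoopState(pattern=pattern, target=target)
    t = 0.0
    grow = 0
    for it in range(fb.max_iterations):
        rho = _measure(pop, state.pattern, resp, sim_cfg, fb, target.shape, light_px)
        rho_s = percentile_rescale(rho, target)
        d = distance(rho_s, target)
        active = t + fb.period_s >= fb_on_after
        state.times.append(t + fb.period_s)
        state.dist.append(d)
        state.fb_active.append(bool(active))
        state.densities.append(rho_s)
        state.iteration = it + 1
        if active and fb.gain > 0:
            state.pattern = update_pattern(state.pattern, rho_s, target, fb)
        if len(state.dist) >= 2 and d > state.dist[-2]:
            grow += 1
            if grow >= fb.divergence_patience and active:
                state.diverged = True
                warnings.warn(
                    "distance grew for "
                    f"{grow} consecutive iterations; consider reducing the gain"
                )
        else:
            grow = 0
        t += fb.period_s
    return state


@dataclass
class MorphResult:
    """Morphing trajectory after a target swap, with the exponential fit."""

    state: LoopState
    dist_new: np.ndarray
    dist_old: np.ndarray
    times: np.ndarray
    tau_s: float
    r_squared: float


def morph(
    pop: AgentPopulation,
    sim_cfg: SimConfig,
    resp: IntensityResponse,
    state: LoopState,
    new_target: np.ndarray,
    fb: FeedbackConfig,
    n_iterations: int,
) -> MorphResult:
    """Swap the loop's target and track the approach to the new one.

    Continues the feedback from ``state`` with the new target, recording the
    distance to both the old and the new target each iteration, then fits
    ``a * exp(-t/tau) + c`` to the distance-to-new decay and reports the
    time constant and the fit's R^2.
    """
    new_target = np.asarray(new_target, dtype=float)
    old_target = state.target
    if new_target.shape != old_target.shape:
        raise ValueError("new target grid must match the old one")
    light_px = sim_cfg.box[0] / new_target.shape[1]
    d_new, d_old, times = [], [], []
    t = state.times[-1] if state.times else 0.0
    for _ in range(n_iterations):
        rho = _measure(pop, state.pattern, resp, sim_cfg, fb, new_target.shape, light_px)
        rho_s = percentile_rescale(rho, new_target)
        d_new.append(distance(rho_s, new_target))
        d_old.append(distance(percentile_rescale(rho, old_target), old_target))
        t += fb.period_s
        times.append(t)
        state.pattern = update_pattern(state.pattern, rho_s, new_target, fb)
        state.densities.append(rho_s)
    state.target = new_target
    d_new = np.asarray(d_new)
    d_old = np.asarray(d_old)
    times = np.asarray(times)
    tt = times - times[0]
    try:
        popt, _ = curve_fit(
            lambda x, a, tau, c: a * np.exp(-x / tau) + c,
            tt, d_new,
            p0=[max(d_new[0] - d_new[-1], 1e-6), max(tt[-1] / 3.0, 1.0), d_new[-1]],
            bounds=([0.0, 1e-3, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        fitted = popt[0] * np.exp(-tt / popt[1]) + popt[2]
        ss_res = float(np.sum((d_new - fitted) ** 2))
        ss_tot = float(np.sum((d_new - d_new.mean()) ** 2))
        tau, r2 = float(popt[1]), 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    except RuntimeError:  # pragma: no cover
        tau, r2 = float("nan"), 0.0
    return MorphResult(
        state=state, dist_new=d_new, dist_old=d_old, times=times,
        tau_s=tau, r_squared=r2,
    )
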