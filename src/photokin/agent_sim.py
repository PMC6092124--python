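"""Stochastic simulation of photokinetic swimmers in a 2-D light landscape.

Synthetic-data generator: N independent agents move in a rectangular box
under a grayscale light pattern.  Motile agents are smooth swimmers whose
heading diffuses with decorrelation time ``tau_rot`` (optionally with
Poissonian tumbles every ``tau_run``); their commanded speed is
``v_i = v_i_sat * f(I(r))`` (homogeneous growth law, Schultz-distributed
saturation speeds) and their *actual* speed carries the two-timescale
memory: a fraction ``beta`` responds instantly, the rest is an exponential
moving average with time constant ``tau_m`` along the trajectory — the
per-agent equivalent of the normalized exponential memory kernel.
Non-motile (non-responsive) agents take Brownian steps with diffusivity
``D_brownian``.

Interactions (steric, hydrodynamic), growth and z-dynamics are deliberately
absent; every observable of interest is a 2-D projected density.  Euler–
Maruyama integration; positions are wrapped (periodic) or reflected at the
box walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .light_response import IntensityResponse, MemoryParams

__all__ = [
    "SimConfig",
    "AgentPopulation",
    "sample_schultz",
    "init_population",
    "step",
    "run_to_stationary",
    "density_histogram",
]


@dataclass
class SimConfig:
    """Simulation parameters (lengths um, times s).

    ``mem=None`` disables memory (instantaneous response).  ``tau_run=None``
    disables tumbling (smooth swimmer).  ``boundary`` is ``"periodic"``
    (default; avoids edge depletion) or ``"reflecting"``.

    ``projection_3d=True`` emulates the projection of swimmers with 3-D
    isotropic headings onto the image plane: each motile agent keeps a fixed
    polar angle (cosine uniform on the sphere) and displaces with
    ``v * sin(psi)``, so the in-plane velocity statistics — hence the
    measured ISF — are those of 3-D swimmers, sinc(qvt) rather than the
    planar J0(qvt).  Use it when generating stacks for DDM; leave it off for
    planar density studies.
    """

    box: tuple[float, float] = (480.0, 480.0)
    dt: float = 0.07
    n_agents: int = 20_000
    alpha_motile: float = 0.5
    tau_rot: float = 20.0
    tau_run: float | None = None
    mean_sat_speed: float = 8.0
    Z: float = 3.0
    mem: MemoryParams | None = None
    D_brownian: float = 0.3
    seed: int = 0
    boundary: str = "periodic"
    projection_3d: bool = False

    def validate(self, pixel_size: float = 2.0) -> None:
        """Raise ValueError naming any violated time-step or sanity constraint."""
        problems = []
        if self.n_agents <= 0:
            problems.append("n_agents must be positive")
        if self.dt <= 0:
            problems.append("dt must be positive")
        if not (0.0 <= self.alpha_motile <= 1.0):
            problems.append("alpha_motile must lie in [0, 1]")
        if self.tau_rot <= 0:
            problems.append("tau_rot must be positive")
        if self.mean_sat_speed <= 0:
            problems.append("mean_sat_speed must be positive")
        if self.Z <= -1:
            problems.append("Z must exceed -1")
        if self.D_brownian < 0:
            problems.append("D_brownian must be non-negative")
        if self.boundary not in ("periodic", "reflecting"):
            problems.append("boundary must be 'periodic' or 'reflecting'")
        if self.dt > 0 and self.alpha_motile > 0:
            # fast agents must not cross more than one light pixel per step
            v_hi = stats.gamma.ppf(
                0.999, self.Z + 1.0, scale=self.mean_sat_speed / (self.Z + 1.0)
            )
            if v_hi * self.dt > pixel_size:
                problems.append(
                    f"dt*v_999={v_hi * self.dt:.2f} um exceeds one light pixel "
                    f"({pixel_size} um); reduce dt below {pixel_size / v_hi:.3f} s"
                )
            if self.dt > self.tau_rot / 20.0:
                problems.append("dt must be <= tau_rot/20")
            if self.mem is not None and self.dt > self.mem.tau_m / 20.0:
                problems.append("dt must be <= tau_m/20")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class AgentPopulation:
    """State arrays for N agents plus the simulation RNG (mutated in place by `step`)."""

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    v_sat: np.ndarray
    m: np.ndarray          # memory state, um/s
    motile: np.ndarray     # bool
    sin_psi: np.ndarray    # in-plane projection factor (1 unless projection_3d)
    speed: np.ndarray      # actual speed at the last step, um/s (0 for non-motile)
    rng: np.random.Generator = field(repr=False)

    @property
    def n(self) -> int:
        return self.x.size


def sample_schultz(rng: np.random.Generator, mean: float, Z: float, size: int) -> np.ndarray:
    """Sample Schultz-distributed speeds: gamma with shape Z+1, mean ``mean``."""
    if mean <= 0 or Z <= -1:
        raise ValueError("require mean > 0 and Z > -1")
    return rng.gamma(shape=Z + 1.0, scale=mean / (Z + 1.0), size=size)


def _light_at(pop_x, pop_y, light: np.ndarray, pixel_size: float) -> np.ndarray:
    ny, nx = light.shape
    ix = np.clip((pop_x / pixel_size).astype(np.intp), 0, nx - 1)
    iy = np.clip((pop_y / pixel_size).astype(np.intp), 0, ny - 1)
    return light[iy, ix]


def init_population(
    cfg: SimConfig,
    resp: IntensityResponse,
    light: np.ndarray | None = None,
    pixel_size: float = 2.0,
) -> AgentPopulation:
    """Initialize agents: uniform positions/headings, Schultz saturation speeds.

    Memory starts fully adapted to the initial light pattern (the experiment
    pre-exposes the sample to uniform bright light for several minutes); with
    ``light=None`` agents start adapted to saturating illumination.
    """
    cfg.validate(pixel_size)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_agents
    Lx, Ly = cfg.box
    x = rng.uniform(0.0, Lx, n)
    y = rng.uniform(0.0, Ly, n)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    v_sat = sample_schultz(rng, cfg.mean_sat_speed, cfg.Z, n)
    motile = rng.random(n) < cfg.alpha_motile
    if cfg.projection_3d:
        sin_psi = np.sqrt(1.0 - rng.uniform(-1.0, 1.0, n) ** 2)
    else:
        sin_psi = np.ones(n)
    if light is None:
        V0 = v_sat.copy()  # f(inf) = 1
    else:
        V0 = v_sat * resp.f(_light_at(x, y, light, pixel_size))
    return AgentPopulation(
        x=x, y=y, theta=theta, v_sat=v_sat, m=V0,
        motile=motile, sin_psi=sin_psi, speed=np.where(motile, V0, 0.0), rng=rng,
    )


def step(
    pop: AgentPopulation,
    light: np.ndarray,
    resp: IntensityResponse,
    cfg: SimConfig,
    pixel_size: float = 2.0,
) -> AgentPopulation:
    """Advance all agents by one Euler–Maruyama step of ``cfg.dt`` (in place).

    Motile agents: commanded speed from the local light, memory update,
    displacement along the heading, rotational diffusion (plus optional
    tumbles).  Non-motile agents: Brownian steps.  Boundary applied last.
    """
    dt = cfg.dt
    rng = pop.rng
    mot = pop.motile
    n = pop.n

    V = pop.v_sat * resp.f(_light_at(pop.x, pop.y, light, pixel_size))
    if cfg.mem is None:
        v_act = V
    else:
        v_act = cfg.mem.beta * V + (1.0 - cfg.mem.beta) * pop.m
        pop.m += dt * (V - pop.m) / cfg.mem.tau_m
    pop.speed = np.where(mot, v_act, 0.0)

    v_xy = v_act * pop.sin_psi
    dx = np.where(mot, v_xy * dt * np.cos(pop.theta), 0.0)
    dy = np.where(mot, v_xy * dt * np.sin(pop.theta), 0.0)
    if cfg.D_brownian > 0:
        sig = np.sqrt(2.0 * cfg.D_brownian * dt)
        brn = ~mot
        dx = dx + np.where(brn, sig * rng.standard_normal(n), 0.0)
        dy = dy + np.where(brn, sig * rng.standard_normal(n), 0.0)
    pop.x += dx
    pop.y += dy

    pop.theta += np.where(
        mot, np.sqrt(2.0 * dt / cfg.tau_rot) * rng.standard_normal(n), 0.0
    )
    if cfg.tau_run is not None:
        tumble = mot & (rng.random(n) < dt / cfg.tau_run)
        if tumble.any():
            pop.theta[tumble] = rng.uniform(0.0, 2.0 * np.pi, int(tumble.sum()))

    Lx, Ly = cfg.box
    if cfg.boundary == "periodic":
        pop.x %= Lx
        pop.y %= Ly
    else:  # reflecting
        for arr, L, flip in ((pop.x, Lx, "x"), (pop.y, Ly, "y")):
            low = arr < 0.0
            high = arr > L
            arr[low] = -arr[low]
            arr[high] = 2.0 * L - arr[high]
            if flip == "x":
                pop.theta[low | high] = np.pi - pop.theta[low | high]
            else:
                pop.theta[low | high] = -pop.theta[low | high]
        np.clip(pop.x, 0.0, Lx, out=pop.x)
        np.clip(pop.y, 0.0, Ly, out=pop.y)
    return pop


def run_to_stationary(
    pop: AgentPopulation,
    light: np.ndarray,
    resp: IntensityResponse,
    cfg: SimConfig,
    t_total: float,
    t_burn: float,
    sample_every: float,
    pixel_size: float = 2.0,
) -> np.ndarray:
    """Run the simulation and return post-burn-in position snapshots.

    Returns an array of shape ``(n_snapshots, n_agents, 2)`` with columns
    (x, y); agent count is conserved at every snapshot by construction.
    """
    if t_total <= t_burn:
        raise ValueError("t_total must exceed t_burn")
    n_steps = int(round(t_total / cfg.dt))
    every = max(1, int(round(sample_every / cfg.dt)))
    burn_steps = int(round(t_burn / cfg.dt))
    snaps = []
    for i in range(1, n_steps + 1):
        step(pop, light, resp, cfg, pixel_size)
        if i > burn_steps and (i - burn_steps) % every == 0:
            snaps.append(np.column_stack([pop.x, pop.y]))
    if not snaps:
        raise ValueError("no snapshots collected; check t_total/t_burn/sample_every")
    return np.stack(snaps)


def density_histogram(
    positions: np.ndarray,
    grid_shape: tuple[int, int],
    box: tuple[float, float],
) -> np.ndarray:
    """Normalized 2-D number density from positions (mean exactly 1).

    ``positions`` is ``(..., N, 2)``: extra leading axes (time snapshots)
    are pooled, i.e. the histogram is time-averaged.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    if pos.size == 0:
        raise ValueError("empty position array")
    ny, nx = grid_shape
    Lx, Ly = box
    counts, _, _ = np.histogram2d(
        pos[:, 1], pos[:, 0], bins=(ny, nx), range=((0.0, Ly), (0.0, Lx))
    )
    return counts / counts.mean()
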