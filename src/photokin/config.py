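"""Run configuration: nested, validated, YAML round-trippable.

One `RunConfig` holds every tunable of the pipeline in nested sections.
Loading is strict — unknown keys are rejected with their names — and an
empty file yields all defaults.  Every pipeline run echoes its resolved
config (plus seed and package version) into a JSON manifest so any artifact
can be regenerated from its manifest alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .agent_sim import SimConfig
from .ddm import DDMCurves  # noqa: F401  (re-export convenience)
from .feedback import FeedbackConfig
from .imaging import RenderConfig
from .light_response import IntensityResponse, MemoryParams

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration schema or constraint violation."""


@dataclass
class ResponseSection:
    v_dark: float = 2.0
    v_sat: float = 8.0
    I_half: float = 50.0
    sigma_ratio: float = 0.5            # sigma = r * v across intensities
    level_to_power_mW_mm2: float = 4e-3  # 8-bit level -> projected power density

    def build(self) -> IntensityResponse:
        return IntensityResponse(self.v_dark, self.v_sat, self.I_half)


@dataclass
class MemorySection:
    enabled: bool = True
    beta: float = 0.44
    tau_m: float = 35.0

    def build(self) -> MemoryParams | None:
        return MemoryParams(self.beta, self.tau_m) if self.enabled else None


@dataclass
class SimSection:
    box: tuple[float, float] = (480.0, 480.0)
    dt: float = 0.07
    n_agents: int = 20_000
    alpha_motile: float = 0.5
    tau_rot: float = 20.0
    tau_run: float | None = None
    mean_sat_speed: float = 8.0
    Z: float = 3.0
    D_brownian: float = 0.3
    boundary: str = "periodic"


@dataclass
class RenderSection:
    psf_sigma: float = 1.0
    counts_per_agent: float = 50.0
    stray_background: float = 5.0
    brightfield_level: float = 100.0
    gaussian_noise_sd: float = 0.5
    poisson: bool = False

    def build(self) -> RenderConfig:
        return RenderConfig(
            psf_sigma=self.psf_sigma,
            counts_per_agent=self.counts_per_agent,
            stray_background=self.stray_background,
            brightfield_level=self.brightfield_level,
            gaussian_noise_sd=self.gaussian_noise_sd,
            poisson=self.poisson,
        )


@dataclass
class DDMSection:
    q_min: float = 0.45
    q_max: float = 1.2
    frame_interval: float = 0.05
    n_frames: int = 1000


@dataclass
class FeedbackSection:
    gain: float = 50.0
    period_s: float = 20.0
    quantize: bool = True
    max_iterations: int = 40
    measure_every_s: float = 1.0
    smooth_sigma_px: float = 1.0
    bounds: tuple[float, float] = (0.0, 255.0)

    def build(self) -> FeedbackConfig:
        return FeedbackConfig(
            gain=self.gain,
            period_s=self.period_s,
            bounds=tuple(self.bounds),
            quantize=self.quantize,
            max_iterations=self.max_iterations,
            measure_every_s=self.measure_every_s,
            smooth_sigma_px=self.smooth_sigma_px,
        )


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    pixel_size_um: float = 2.0
    response: ResponseSection = field(default_factory=ResponseSection)
    memory: MemorySection = field(default_factory=MemorySection)
    sim: SimSection = field(default_factory=SimSection)
    render: RenderSection = field(default_factory=RenderSection)
    ddm: DDMSection = field(default_factory=DDMSection)
    feedback: FeedbackSection = field(default_factory=FeedbackSection)

    def make_sim_config(self, seed: int | None = None) -> SimConfig:
        """Assemble a validated `SimConfig` (memory section folded in)."""
        cfg = SimConfig(
            box=tuple(self.sim.box),
            dt=self.sim.dt,
            n_agents=self.sim.n_agents,
            alpha_motile=self.sim.alpha_motile,
            tau_rot=self.sim.tau_rot,
            tau_run=self.sim.tau_run,
            mean_sat_speed=self.sim.mean_sat_speed,
            Z=self.sim.Z,
            mem=self.memory.build(),
            D_brownian=self.sim.D_brownian,
            seed=self.seed if seed is None else seed,
            boundary=self.sim.boundary,
        )
        cfg.validate(self.pixel_size_um)
        return cfg

    def validate(self) -> None:
        try:
            self.response.build()
            self.memory.build()
            self.make_sim_config()
            self.render.build()
            self.feedback.build()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(dataclasses.asdict(self))


def _from_dict(cls, data: dict, path: str = ""):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = path or cls.__name__
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.default_factory, type) and dataclasses.is_dataclass(f.default_factory)
        ):
            sub_cls = f.default_factory
            if not isinstance(value, dict):
                raise ConfigError(f"section {path + name} must be a mapping")
            kwargs[name] = _from_dict(sub_cls, value, path + name + ".")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; empty file means all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    cfg = _from_dict(RunConfig, data)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    """Serialize a config to YAML (round-trips losslessly through load_config)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
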