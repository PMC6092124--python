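"""Light-to-speed response of photokinetic swimmers.

Proteorhodopsin-expressing cells swim with a speed set by the local light
intensity: the light-driven proton pump feeds the proton-motive force that
powers the flagellar motor.  Three empirical facts are modelled here:

1. The population-mean speed follows a saturating (hyperbolic) curve of the
   projected intensity, ``v(I) = v_dark + (v_sat - v_dark) * I / (I + I_half)``.
2. The speed standard deviation is proportional to the mean across the whole
   intensity range, which is what one expects if every cell obeys a
   *homogeneous growth law* ``v_i(I) = v_i^sat * f(I)`` with a shared
   dimensionless response ``f`` saturating at one.  The per-cell saturation
   speeds are Schultz (gamma) distributed with shape ``Z = (v/sigma)**2 - 1``.
3. The temporal response to an intensity step is two-step: an instantaneous
   jump covering a fraction ``beta`` of the total change, followed by an
   exponential relaxation with a single time constant ``tau_m`` (the slow
   component is attributed to ATP-synthase and stator dynamics; none of that
   machinery is modelled mechanistically here).

Intensities may be expressed in physical units (mW/mm^2) or raw 8-bit
projector levels; only the ratio ``I / I_half`` enters the model, so the two
conventions differ by the single calibration scalar kept in the run config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FitFailure",
    "IntensityResponse",
    "MemoryParams",
    "StepResponseFit",
    "mean_speed",
    "speed_std",
    "schultz_shape",
    "step_response",
    "square_wave_response",
    "fit_step_response",
]


class FitFailure(RuntimeError):
    """A nonlinear fit did not converge or the data cannot identify the model."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class IntensityResponse:
    """Hyperbolic speed-versus-intensity curve with dark baseline and saturation.

    Parameters
    ----------
    v_dark:
        Population-mean speed at zero light (um/s).
    v_sat:
        Population-mean speed in saturating light (um/s); must exceed `v_dark`.
    I_half:
        Intensity at which the response has risen halfway, in the same units
        as the intensities passed to :meth:`mean_speed` (8-bit projector
        levels by default).
    """

    v_dark: float = 2.0
    v_sat: float = 8.0
    I_half: float = 50.0

    def __post_init__(self):
        if not (self.v_sat > self.v_dark >= 0.0):
            raise ValueError("require v_sat > v_dark >= 0")
        if self.I_half <= 0:
            raise ValueError("I_half must be positive")

    def mean_speed(self, I):
        """Mean swimming speed (um/s) at intensity ``I`` (monotone, bounded)."""
        I = np.asarray(I, dtype=float)
        if np.any(I < 0):
            raise ValueError("intensity must be non-negative")
        return self.v_dark + (self.v_sat - self.v_dark) * I / (I + self.I_half)

    def f(self, I):
        """Dimensionless per-cell response ``f(I) = v(I)/v_sat`` with ``f(inf)=1``."""
        return self.mean_speed(I) / self.v_sat

    def invert(self, v):
        """Intensity producing mean speed ``v``; defined for v_dark < v < v_sat."""
        v = np.asarray(v, dtype=float)
        if np.any(v <= self.v_dark) or np.any(v >= self.v_sat):
            raise ValueError("speed outside the open range (v_dark, v_sat)")
        return self.I_half * (v - self.v_dark) / (self.v_sat - v)


@dataclass(frozen=True)
class MemoryParams:
    """Two-timescale speed-memory parameters.

    ``beta`` is the fraction of a speed change that happens instantaneously
    (faster than ~1 s time resolution); the remaining ``1 - beta`` relaxes
    exponentially with time constant ``tau_m`` seconds.
    """

    beta: float = 0.44
    tau_m: float = 35.0

    def __post_init__(self):
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")


def mean_speed(I, resp: IntensityResponse):
    """Population-mean swimming speed at intensity ``I``. See :class:`IntensityResponse`."""
    return resp.mean_speed(I)


def speed_std(I, resp: IntensityResponse, r: float):
    """Speed standard deviation at intensity ``I`` under sigma = r * v.

    The proportionality constant ``r`` is the slope of the sigma-vs-v line
    (a line through the origin); a single ``r`` holds across all intensities
    under the homogeneous growth law.
    """
    if r < 0:
        raise ValueError("ratio r must be non-negative")
    return r * resp.mean_speed(I)


def schultz_shape(v: float, sigma: float) -> float:
    """Schultz shape parameter ``Z = (v/sigma)**2 - 1`` of the speed distribution.

    ``Z = 0`` is the exponential distribution; ``Z -> inf`` is monodisperse.
    ``sigma = 0`` is rejected as a degenerate distribution (Z diverges).
    """
    if v <= 0:
        raise ValueError("mean speed must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive (sigma=0 is degenerate, Z -> inf)")
    return (v / sigma) ** 2 - 1.0


def step_response(t, V1: float, V2: float, mem: MemoryParams):
    """Mean speed at time ``t >= 0`` after an intensity step at ``t = 0``.

    History fully adapted to speed ``V1`` for t < 0; the light then commands
    ``V2``.  The response jumps by ``beta * (V2 - V1)`` and relaxes the rest
    exponentially::

        v(t) = V2 - (1 - beta) * (V2 - V1) * exp(-t / tau_m)

    This is the unique response of the normalized exponential-kernel memory
    (unit-mass kernel ``exp(-t'/tau_m)/tau_m``) to a step, so a uniform
    history reproduces itself exactly.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (step occurs at t=0)")
    return V2 - (1.0 - mem.beta) * (V2 - V1) * np.exp(-t / mem.tau_m)


def square_wave_response(t, V1: float, V2: float, mem: MemoryParams, period: float):
    """Periodic steady-state mean speed under square-wave forcing.

    The commanded speed is ``V2`` for the first half period and ``V1`` for the
    second half (period ``period`` seconds), repeated indefinitely; the memory
    state has reached its periodic steady state.  Rising and falling branches
    share the single relaxation time ``tau_m``.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    t = np.mod(np.asarray(t, dtype=float), period)
    half = period / 2.0
    E = np.exp(-half / mem.tau_m)
    # memory state at the start of the high / low half-periods
    m_lo = (V1 + E * V2) / (1.0 + E)
    m_hi = (V2 + E * V1) / (1.0 + E)
    high = t < half
    m = np.where(
        high,
        V2 + (m_lo - V2) * np.exp(-t / mem.tau_m),
        V1 + (m_hi - V1) * np.exp(-(t - half) / mem.tau_m),
    )
    V = np.where(high, V2, V1)
    return mem.beta * V + (1.0 - mem.beta) * m


@dataclass(frozen=True)
class StepResponseFit:
    """Result of :func:`fit_step_response`: plateau speeds, memory parameters, errors."""

    V1: float
    V2: float
    beta: float
    tau_m: float
    stderr: dict
    residual_rms: float

    @property
    def mem(self) -> MemoryParams:
        return MemoryParams(beta=self.beta, tau_m=self.tau_m)


def fit_step_response(
    times, speeds, period: float | None = None, V1: float | None = None
) -> StepResponseFit:
    """Least-squares fit of the jump-plus-exponential response model.

    Parameters
    ----------
    times, speeds:
        Sampled mean-speed trace (s, um/s).  Needs at least 10 samples
        spanning several relaxation times.
    period:
        If given, the forcing is a square wave of this period (high first
        half, low second half, switches at multiples of ``period/2``) and the
        periodic steady-state model is fitted; rising and falling branches
        share one ``tau_m``.  If ``None``, a single step at ``t = 0`` is
        assumed; samples at ``t < 0`` are taken as the adapted pre-step
        baseline.
    V1:
        Pin the pre-step speed instead of fitting it.  In single-step mode a
        trace sampled only at ``t >= 0`` determines ``(1-beta)*(V2-V1)`` but
        not ``beta`` and ``V1`` separately, so either baseline samples or an
        explicit ``V1`` are required.

    Returns
    -------
    StepResponseFit with estimates of (V1, V2, beta, tau_m) and their
    standard errors from the fit covariance.

    Raises
    ------
    FitFailure
        If the trace is constant (beta and tau_m unidentifiable), the
        single-step baseline is missing, or the optimizer fails.
    """
    times = np.asarray(times, dtype=float)
    speeds = np.asarray(speeds, dtype=float)
    if times.shape != speeds.shape or times.ndim != 1:
        raise ValueError("times and speeds must be 1-D arrays of equal length")
    if times.size < 10:
        raise ValueError("need at least 10 samples")
    span = float(np.ptp(times))
    amp = float(np.ptp(speeds))
    scale = float(np.mean(np.abs(speeds))) + 1e-12
    if amp < 1e-9 * scale:
        raise FitFailure(
            "constant speed trace: beta and tau_m are unidentifiable",
            {"amplitude": amp, "scale": scale},
        )

    if period is None:
        if V1 is None and not np.any(times < 0):
            raise FitFailure(
                "single-step trace without pre-step baseline: beta and V1 are "
                "only jointly identifiable; include t<0 samples or pass V1"
            )

        def model(t, v1, V2, beta, tau):
            t = np.asarray(t, dtype=float)
            post = V2 - (1.0 - beta) * (V2 - v1) * np.exp(-np.clip(t, 0.0, None) / tau)
            return np.where(t < 0, v1, post)

        tau0 = max(span / 5.0, 1e-3)
    else:

        def model(t, v1, V2, beta, tau):
            return square_wave_response(t, v1, V2, MemoryParams(beta, tau), period)

        tau0 = max(period / 6.0, 1e-3)

    p0 = [float(np.percentile(speeds, 5)), float(np.percentile(speeds, 95)), 0.5, tau0]
    lo = [0.0, 0.0, 0.0, 1e-6]
    hi = [np.inf, np.inf, 1.0, 100.0 * max(span, tau0)]
    if V1 is not None:  # pin the baseline within a sliver of float slack
        p0[0] = V1
        lo[0] = V1 - 1e-12 * (abs(V1) + 1.0)
        hi[0] = V1 + 1e-12 * (abs(V1) + 1.0)
    try:
        popt, pcov = curve_fit(
            model, times, speeds, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer pathologies
        raise FitFailure(f"step-response fit did not converge: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    resid = speeds - model(times, *popt)
    if not np.all(np.isfinite(popt)):
        raise FitFailure("step-response fit returned non-finite parameters")
    names = ("V1", "V2", "beta", "tau_m")
    return StepResponseFit(
        V1=float(popt[0]),
        V2=float(popt[1]),
        beta=float(popt[2]),
        tau_m=float(popt[3]),
        stderr=dict(zip(names, (float(e) for e in perr))),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
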