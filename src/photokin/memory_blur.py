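"""Memory blur of the light-imposed speed map and the stationary density it predicts.

A self-propelled particle with isotropic reorientation and a space-dependent
speed ``w(r)`` occupies space with stationary density ``rho(r) ~ 1/w(r)``.
When the speed response to light has a finite memory (fraction ``beta``
instantaneous, the rest relaxing over ``tau_m``), a swimmer carries its past
speed along its path, so the *actual* speed map ``w`` is a blurred version of
the instantaneous map ``V(r) = v(I(r))``::

    w = beta * V + (1 - beta) * (gamma * V)        (convolution)

For straight trajectories at the baseline speed, the temporal exponential
kernel becomes a spatial one with decay constant ``k = 1 / (v_bar * tau_m)``
(``v_bar`` the spatial mean of ``V``).  Averaged over 3-D directions the
kernel is ``Gamma(r) = k exp(-k r) / (4 pi r^2)``; for z-invariant light
patterns its z-projection ``gamma(x, y)`` has no closed real-space form but a
simple 2-D Fourier transform::

    gamma_tilde(q) = (k / q) * arctan(q / k)

so the blur is evaluated in Fourier space.  The stationary normalized
density for a motile (light-responsive) fraction ``alpha`` is then::

    rho*(r) = alpha * ( w(r)^-1 / mean(w^-1) - 1 ) + 1

which has spatial mean exactly one by construction; the non-responsive
fraction ``1 - alpha`` contributes the flat baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "kernel_ft",
    "kernel_3d",
    "blur_speed_map",
    "predict_density",
    "density_vs_inverse_speed",
    "fit_density_line",
    "LineFit",
]


def kernel_ft(q, k: float):
    """Fourier transform ``gamma_tilde(q) = (k/q) arctan(q/k)`` of the projected kernel.

    ``q`` is the modulus of the 2-D wave vector (um^-1, may be an array),
    ``k`` the inverse memory length (um^-1).  Continuous at ``q = 0`` where
    the value is 1 (unit-mass kernel); monotone decreasing in ``q`` and
    bounded in (0, 1].
    """
    if k <= 0:
        raise ValueError("k must be positive")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(q == 0.0, 1.0, (k / np.where(q == 0.0, 1.0, q)) * np.arctan(q / k))
    return out if out.ndim else float(out)


def kernel_3d(r, k: float):
    """Isotropic 3-D memory kernel ``Gamma(r) = k exp(-k r) / (4 pi r^2)`` (um^-3).

    Normalized to unit mass over all space; singular (non-integrable
    pointwise) at the origin, so ``r = 0`` is rejected.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive (kernel is singular at r=0)")
    out = k * np.exp(-k * r) / (4.0 * np.pi * r**2)
    return out if out.ndim else float(out)


def blur_speed_map(
    V: np.ndarray,
    beta: float,
    *,
    k: float | None = None,
    tau_m: float | None = None,
    pixel_size: float = 2.0,
    boundary: str = "periodic",
) -> np.ndarray:
    """Blurred (actual) speed map ``w = beta V + (1-beta) gamma * V``.

    Parameters
    ----------
    V:
        2-D instantaneous speed map (um/s), all entries positive.
    beta:
        Instantaneous response fraction in [0, 1]; ``beta = 1`` returns ``V``.
    k:
        Inverse blur length (um^-1).  If ``None`` it is set from the map
        itself as ``k = 1 / (mean(V) * tau_m)``.
    tau_m:
        Memory time (s); required when ``k`` is not given.
    pixel_size:
        Grid spacing of ``V`` in um.
    boundary:
        ``"periodic"`` (circular convolution; matches the analytic
        plane-wave eigenfunctions) or ``"mirror"`` (even symmetric
        extension, for finite fields of view).
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-D array")
    if not np.all(np.isfinite(V)) or np.any(V <= 0):
        raise ValueError("speed map must be finite and strictly positive")
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    if k is None:
        if tau_m is None:
            raise ValueError("provide either k or tau_m")
        k = 1.0 / (float(V.mean()) * float(tau_m))
    if k <= 0:
        raise ValueError("k must be positive")
    if beta == 1.0:
        return V.copy()

    if boundary == "periodic":
        work = V
    elif boundary == "mirror":
        # even periodic extension: doubled grid is smooth across the seams
        work = np.concatenate([V, V[::-1, :]], axis=0)
        work = np.concatenate([work, work[:, ::-1]], axis=1)
    else:
        raise ValueError("boundary must be 'periodic' or 'mirror'")

    ny, nx = work.shape
    qy = 2.0 * np.pi * np.fft.fftfreq(ny, d=pixel_size)
    qx = 2.0 * np.pi * np.fft.rfftfreq(nx, d=pixel_size)
    Q = np.hypot(qy[:, None], qx[None, :])
    transfer = beta + (1.0 - beta) * kernel_ft(Q, k)
    w = np.fft.irfft2(np.fft.rfft2(work) * transfer, s=work.shape)
    if boundary == "mirror":
        w = w[: V.shape[0], : V.shape[1]]
    return w


def predict_density(w: np.ndarray, alpha: float) -> np.ndarray:
    """Stationary normalized density predicted from the actual speed map.

    ``rho*(r) = alpha * (w^-1 / mean(w^-1) - 1) + 1``; the responsive
    fraction ``alpha`` accumulates as 1/w, the rest stays flat.  The output
    has spatial mean exactly 1 (up to float rounding).
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("speed map must be finite and strictly positive")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    inv = 1.0 / w
    return alpha * (inv / inv.mean() - 1.0) + 1.0


def density_vs_inverse_speed(
    rho: np.ndarray, speed: np.ndarray, levels: np.ndarray
) -> pd.DataFrame:
    """Level-averaged density versus inverse local mean speed.

    Groups the pixels of the normalized density map ``rho`` by the intensity
    level labels ``levels`` (integer map congruent with ``rho``), averages
    density within each level, and pairs it with the inverse of the level's
    mean speed from the speed map.  The resulting table is what one fits a
    straight line through: the high-speed branch has slope
    ``alpha / mean(w^-1)`` and intercept ``1 - alpha``.

    Returns a DataFrame sorted by ``inv_speed_s_um`` with columns
    ``level, speed_um_s, inv_speed_s_um, mean_density, sd_density, n_pixels``.
    """
    rho = np.asarray(rho, dtype=float)
    speed = np.asarray(speed, dtype=float)
    levels = np.asarray(levels)
    if not (rho.shape == speed.shape == levels.shape):
        raise ValueError("rho, speed and levels must have congruent shapes")
    rows = []
    for lev in np.unique(levels):
        mask = levels == lev
        n = int(mask.sum())
        if n == 0:  # pragma: no cover - unique() never yields empty levels
            warnings.warn(f"level {lev} has no pixels; excluded")
            continue
        v = float(speed[mask].mean())
        rows.append(
            {
                "level": lev,
                "speed_um_s": v,
                "inv_speed_s_um": 1.0 / v,
                "mean_density": float(rho[mask].mean()),
                "sd_density": float(rho[mask].std()),
                "n_pixels": n,
            }
        )
    if len(rows) < 2:
        raise ValueError("need at least 2 levels")
    return pd.DataFrame(rows).sort_values("inv_speed_s_um", ignore_index=True)


@dataclass(frozen=True)
class LineFit:
    """Straight-line fit ``mean_density = slope * inv_speed + intercept``."""

    slope: float
    intercept: float
    stderr_slope: float
    stderr_intercept: float
    r_value: float
    n_points: int


def fit_density_line(table: pd.DataFrame, n_high: int | None = None) -> LineFit:
    """Linear fit of level-averaged density against inverse speed.

    ``n_high`` restricts the fit to the ``n_high`` highest-speed levels
    (smallest inverse speed), mirroring the fit of the high-speed branch
    where the instantaneous 1/v law holds; ``None`` uses all levels.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 levels to fit a line")
    sub = table.nsmallest(n_high, "inv_speed_s_um") if n_high else table
    if len(sub) < 2:
        raise ValueError("n_high leaves fewer than 2 points; fit refused")
    res = stats.linregress(sub["inv_speed_s_um"], sub["mean_density"])
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr_slope=float(res.stderr),
        stderr_intercept=float(res.intercept_stderr),
        r_value=float(res.rvalue),
        n_points=len(sub),
    )
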