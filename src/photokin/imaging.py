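"""Microscope-like rendering and the density image-analysis chain.

The renderer is the second synthetic-data generator: it turns agent
positions into camera-like frames.  Dark-field frames are additive Gaussian
splats on a low stray background (signal proportional to local cell count),
bright-field frames are signed-contrast spots on a gray background, as the
structure-function definition of DDM expects.  Both can be modulated by a
smooth illumination envelope and carry Poisson and/or Gaussian noise.

The analysis chain mirrors standard dark-field densitometry: a flat-field
reference rho0 (frame average followed by a wide Gaussian blur, sigma about
100 um) captures the illumination envelope; dividing a raw time-averaged
frame by rho0 gives the normalized density rho* (flat and about 1 for a
uniform sample).  Maps are compared to a target after an affine rescaling
that matches the 10th and 90th percentiles of the two histograms, and the
distance is the root of the summed squared pixel differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "RenderConfig",
    "render_darkfield",
    "render_brightfield",
    "render_stack",
    "flatfield_reference",
    "normalize_density",
    "background_subtract",
    "percentile_rescale",
    "distance",
]


@dataclass
class RenderConfig:
    """Rendering parameters.

    ``psf_sigma`` um; ``counts_per_agent`` is the integrated signal of one
    cell (dark-field) or the contrast amplitude (bright-field);
    ``envelope`` is an optional smooth 2-D gain field (broadcastable to the
    frame); noise is Gaussian with sd ``gaussian_noise_sd`` plus optional
    Poisson shot noise.
    """

    psf_sigma: float = 1.0
    counts_per_agent: float = 50.0
    stray_background: float = 5.0
    brightfield_level: float = 100.0
    envelope: np.ndarray | None = None
    gaussian_noise_sd: float = 0.5
    poisson: bool = False

    def __post_init__(self):
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.gaussian_noise_sd < 0:
            raise ValueError("gaussian_noise_sd must be non-negative")


def _splat(positions, grid_shape, pixel_size, psf_sigma_px):
    # bilinear (cloud-in-cell) deposition: sub-pixel positioning matters for
    # DDM, where nearest-pixel snapping would alias swimmer displacements
    ny, nx = grid_shape
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    gx = pos[:, 0] / pixel_size - 0.5
    gy = pos[:, 1] / pixel_size - 0.5
    ix = np.floor(gx).astype(np.intp)
    iy = np.floor(gy).astype(np.intp)
    fx = gx - ix
    fy = gy - iy
    counts = np.zeros((ny, nx))
    for dy_, dx_, wgt in (
        (0, 0, (1 - fx) * (1 - fy)),
        (0, 1, fx * (1 - fy)),
        (1, 0, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        np.add.at(counts, ((iy + dy_) % ny, (ix + dx_) % nx), wgt)
    return gaussian_filter(counts, psf_sigma_px, mode="wrap")


def render_darkfield(
    positions: np.ndarray,
    grid_shape: tuple[int, int],
    pixel_size: float,
    cfg: RenderConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Dark-field frame: PSF splats + stray background, times envelope, plus noise.

    In the noiseless, flat-envelope limit the intensity above background is
    proportional to the local cell count (integral ``counts_per_agent`` per
    agent; the PSF filter conserves it).
    """
    img = cfg.counts_per_agent * _splat(
        positions, grid_shape, pixel_size, cfg.psf_sigma / pixel_size
    )
    img = img + cfg.stray_background
    if cfg.envelope is not None:
        img = img * cfg.envelope
    return _add_noise(img, cfg, rng)


def render_brightfield(
    positions: np.ndarray,
    grid_shape: tuple[int, int],
    pixel_size: float,
    cfg: RenderConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bright-field frame: dark (negative-contrast) spots on a gray background."""
    img = cfg.brightfield_level - cfg.counts_per_agent * _splat(
        positions, grid_shape, pixel_size, cfg.psf_sigma / pixel_size
    )
    if cfg.envelope is not None:
        img = img * cfg.envelope
    return _add_noise(img, cfg, rng)


def _add_noise(img, cfg: RenderConfig, rng):
    if cfg.poisson or cfg.gaussian_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        if cfg.poisson:
            img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        if cfg.gaussian_noise_sd > 0:
            img = img + cfg.gaussian_noise_sd * rng.standard_normal(img.shape)
    return img


def render_stack(
    positions_ts: np.ndarray,
    grid_shape: tuple[int, int],
    pixel_size: float,
    cfg: RenderConfig,
    mode: str = "darkfield",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a time series of position snapshots into a (T, H, W) stack."""
    fn = {"darkfield": render_darkfield, "brightfield": render_brightfield}
    if mode not in fn:
        raise ValueError("mode must be 'darkfield' or 'brightfield'")
    if rng is None:
        rng = np.random.default_rng()
    return np.stack(
        [fn[mode](p, grid_shape, pixel_size, cfg, rng) for p in positions_ts]
    )


def flatfield_reference(
    frames: np.ndarray, pixel_size: float, sigma_um: float = 100.0
) -> np.ndarray:
    """Flat-field map rho0: frame average blurred with a wide Gaussian.

    Acquired on a homogeneous sample (default kernel sd 100 um); the blur
    preserves the image mean and must leave every pixel strictly positive,
    since raw frames are later divided by rho0.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames for a flat-field reference")
    rho0 = gaussian_filter(frames.mean(axis=0), sigma_um / pixel_size, mode="nearest")
    if np.any(rho0 <= 0):
        raise ValueError("flat-field reference has non-positive values; cannot divide")
    return rho0


def normalize_density(raw: np.ndarray, rho0: np.ndarray) -> np.ndarray:
    """Normalized density rho* = raw / rho0 (pixelwise flat-field correction)."""
    raw = np.asarray(raw, dtype=float)
    rho0 = np.asarray(rho0, dtype=float)
    if raw.shape != rho0.shape:
        raise ValueError("raw frame and flat-field shapes differ")
    if np.any(rho0 <= 0):
        raise ValueError("flat-field reference must be strictly positive")
    return raw / rho0


def background_subtract(frame: np.ndarray, percentile: float = 5.0) -> np.ndarray:
    """Subtract the frame's 5th-percentile intensity, clipping at zero.

    Percentiles use linear interpolation between order statistics.  Clipping
    keeps dark-field intensities non-negative.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    return np.clip(frame - np.percentile(frame, percentile), 0.0, None)


def percentile_rescale(
    rho_star: np.ndarray, target: np.ndarray, lo: float = 10.0, hi: float = 90.0
) -> np.ndarray:
    """Affine rescale of rho* so its 10th/90th percentiles match the target's.

    ``rho_s = s (rho* - p_lo) + t_lo`` with ``s = (t_hi - t_lo)/(p_hi - p_lo)``.
    Invariant under positive affine maps of the input; a degenerate histogram
    (equal percentiles) is rejected.
    """
    rho_star = np.asarray(rho_star, dtype=float)
    target = np.asarray(target, dtype=float)
    p_lo, p_hi = np.percentile(rho_star, [lo, hi])
    t_lo, t_hi = np.percentile(target, [lo, hi])
    if p_hi == p_lo:
        raise ValueError("degenerate histogram: equal percentiles, cannot rescale")
    return (t_hi - t_lo) / (p_hi - p_lo) * (rho_star - p_lo) + t_lo


def distance(rho_s: np.ndarray, target: np.ndarray, normalize_by: float | None = None) -> float:
    """Root of the summed squared pixel differences between two maps.

    ``normalize_by`` divides the result (e.g. by the initial distance, for
    trajectories reported relative to their starting value).
    """
    rho_s = np.asarray(rho_s, dtype=float)
    target = np.asarray(target, dtype=float)
    if rho_s.shape != target.shape:
        raise ValueError("map shapes differ")
    d = float(np.sqrt(np.sum((rho_s - target) ** 2)))
    if normalize_by is not None:
        if normalize_by <= 0:
            raise ValueError("normalize_by must be positive")
        d /= normalize_by
    return d
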