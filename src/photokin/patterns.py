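"""Light-pattern builders and PNG I/O.

Patterns are 2-D float arrays of projector intensity (8-bit levels by
convention, physical pixel 2 um); builders also return an integer label map
when the pattern is made of discrete levels, which is what the
level-averaged density analysis consumes.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = [
    "chessboard",
    "stripes",
    "two_level_stripes",
    "load_pattern_png",
    "save_pattern_png",
]


def chessboard(
    n_tiles: tuple[int, int] = (12, 12),
    tile_px: int = 20,
    levels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-level chessboard: tiles cycle through the intensity levels.

    With ``n_tiles`` a multiple of ``len(levels)`` every level covers the
    same area; the cyclic assignment scatters each level across the field
    like the 12-level boards used to probe the speed response.

    Returns ``(intensity, labels)``, both ``(n_tiles[0]*tile_px, n_tiles[1]*tile_px)``.
    """
    if levels is None:
        levels = np.linspace(0.0, 255.0, 12)
    levels = np.asarray(levels, dtype=float)
    ty, tx = n_tiles
    idx = (np.arange(ty)[:, None] * tx + np.arange(tx)[None, :]) % levels.size
    labels = np.kron(idx, np.ones((tile_px, tile_px), dtype=int))
    return levels[labels], labels


def stripes(
    shape_px: tuple[int, int],
    wavelength_px: int,
    lo: float,
    hi: float,
    axis: int = 1,
    profile: str = "square",
) -> np.ndarray:
    """Periodic stripes along ``axis``: square or cosine profile between lo and hi."""
    ny, nx = shape_px
    n = nx if axis == 1 else ny
    x = np.arange(n)
    phase = 2.0 * np.pi * x / wavelength_px
    if profile == "square":
        prof = np.where((x % wavelength_px) < wavelength_px / 2, hi, lo)
    elif profile == "cosine":
        prof = (hi + lo) / 2.0 + (hi - lo) / 2.0 * np.cos(phase)
    else:
        raise ValueError("profile must be 'square' or 'cosine'")
    return np.tile(prof, (ny, 1)) if axis == 1 else np.tile(prof[:, None], (1, nx))


def two_level_stripes(
    shape_px: tuple[int, int], lo: float, hi: float, axis: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """One full square wave across the field (two half-field bands) plus labels."""
    ny, nx = shape_px
    wavelength = nx if axis == 1 else ny
    intensity = stripes(shape_px, wavelength, lo, hi, axis=axis, profile="square")
    labels = (intensity == hi).astype(int)
    return intensity, labels


def load_pattern_png(path) -> np.ndarray:
    """Read a grayscale PNG/PGM as a float intensity pattern (8-bit levels)."""
    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:  # collapse RGB(A) to luminance
        img = img[..., :3].mean(axis=-1)
    return img


def save_pattern_png(path, pattern: np.ndarray) -> None:
    """Write an intensity pattern as an 8-bit grayscale PNG (clipped/rounded)."""
    arr = np.clip(np.rint(np.asarray(pattern, dtype=float)), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)
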