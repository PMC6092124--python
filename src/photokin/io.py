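"""Artifact I/O: float TIFF maps and stacks, CSV tables, JSON run manifests."""

from __future__ import annotations

import json
from importlib import metadata
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "write_map_tiff",
    "read_map_tiff",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_manifest",
    "package_version",
]


def package_version() -> str:
    try:
        return metadata.version("photokin")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def write_map_tiff(path, arr: np.ndarray, pixel_size_um: float | None = None) -> None:
    """Write a 2-D map as 32-bit float TIFF (pixel size in the metadata if given)."""
    meta = {"pixel_size_um": pixel_size_um} if pixel_size_um else None
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32), metadata=meta)


def read_map_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_stack_tiff(
    path,
    frames: np.ndarray,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> None:
    """Write a (T, H, W) stack as multi-page float32 TIFF plus a JSON sidecar."""
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))
    side = {"pixel_size_um": pixel_size_um, "frame_interval_s": frame_interval_s}
    Path(str(path) + ".json").write_text(json.dumps(side))


def read_stack_tiff(path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF stack and its metadata sidecar (empty dict if absent)."""
    frames = tifffile.imread(path).astype(float)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return frames, meta


def write_manifest(path, config_dict: dict, seed: int, **extras) -> None:
    """Echo the resolved configuration, seed and code version next to the outputs."""
    payload = {
        "photokin_version": package_version(),
        "seed": int(seed),
        "config": config_dict,
        **extras,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
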