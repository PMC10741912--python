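"""Raster I/O for holograms, phase maps and height maps.

Holograms are read from single-channel 8/16-bit TIFF or PNG files; height
and phase maps are written as 32-bit float single-channel TIFF (micrometers
or radians), with a CSV form available for small grids.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .exceptions import FormatError, ValidationError
from .phase import HeightMap
from .windowing import Hologram, HologramRole

__all__ = ["read_hologram", "write_hologram", "write_heightmap", "read_heightmap"]

_CSV_MAX_SIDE = 64


def read_hologram(path, expected_role: HologramRole | str = HologramRole.OBJECT) -> Hologram:
    """Load a single-channel 8/16-bit TIFF or PNG as a Hologram."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: expected a single-channel image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(
            f"{path.name}: expected 8- or 16-bit unsigned integers, got {arr.dtype}"
        )
    return Hologram(
        pixels=arr.astype(float), role=HologramRole(expected_role), bit_depth=depth
    )


def write_hologram(h: Hologram, path) -> None:
    """Write a hologram at its recorded bit depth (TIFF or PNG)."""
    path = Path(path)
    dtype = np.uint8 if h.bit_depth == 8 else np.uint16
    arr = np.clip(np.rint(h.pixels), 0, h.full_scale).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_heightmap(h: HeightMap | np.ndarray, path) -> None:
    """Write a height (or phase) map as float-32 TIFF, or CSV for small grids."""
    vals = h.values if isinstance(h, HeightMap) else np.asarray(h, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("height map contains non-finite values")
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if max(vals.shape) > _CSV_MAX_SIDE:
            raise ValidationError(
                f"CSV output is limited to {_CSV_MAX_SIDE}x{_CSV_MAX_SIDE} grids"
            )
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for row in vals:
                writer.writerow([repr(float(x)) for x in row])
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, vals.astype(np.float32))
    else:
        raise ValidationError(f"unsupported height-map format: {path.suffix}")


def read_heightmap(path, pixel_pitch: float = 0.055) -> HeightMap:
    """Read a float TIFF or CSV height map back into a HeightMap."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            vals = np.array([[float(x) for x in row] for row in csv.reader(fh)])
    else:
        vals = np.asarray(tifffile.imread(path), dtype=float)
    return HeightMap(values=vals, pixel_pitch=pixel_pitch)
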