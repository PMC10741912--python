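"""Fourier-domain sideband location, windowing geometry, and random centers.

An off-axis hologram stores the object wavefront in two sideband lobes,
offset from DC by the fringe carrier frequency. Reconstruction isolates a
square region around (a point near) the positive sideband peak, recenters
it on DC (which removes the carrier), and inverse-transforms it.

All frequency-domain arithmetic in this module uses the *centered* layout:
the DC bin sits at index ``(H//2, W//2)``. Coordinates are ``(row, col)``
integer pairs in that layout.

The maximum windowing square around the peak is bounded by four distances:

``a``
    half the horizontal peak-to-DC distance (going further would pull in
    the DC lobe),
``b``
    the horizontal distance to the nearer lateral edge of the spectrum,
``c``, ``d``
    the vertical distances to the top and bottom edges.

The square's side is ``Rm = 2 * min(a, b, c, d)``. A windowed sideband of
side ``SW`` must satisfy ``Rm/2 < SW < Rm``: the lower bound guarantees the
peak stays inside every window whose center lies in the eligible square,
the upper bound keeps every window inside the maximum square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .exceptions import (
    BoundsError,
    DimensionError,
    GeometryError,
    NoSidebandError,
    SamplingError,
    WindowSizeError,
)

__all__ = [
    "Hologram",
    "HologramRole",
    "Spectrum",
    "WindowGeometry",
    "WindowPlan",
    "compute_spectrum",
    "invert_spectrum",
    "locate_sideband_peak",
    "compute_window_geometry",
    "default_window_size",
    "sample_window_centers",
    "extract_windowed_sideband",
]


class HologramRole(str, Enum):
    REFERENCE = "reference"
    OBJECT = "object"


@dataclass(frozen=True)
class Hologram:
    """A recorded interference pattern: nonnegative intensities on a grid."""

    pixels: np.ndarray
    role: HologramRole = HologramRole.OBJECT
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or min(px.shape) < 8:
            raise DimensionError(
                f"hologram must be a 2D grid of at least 8x8 pixels, got shape {px.shape}"
            )
        if np.any(px < 0):
            raise DimensionError("hologram intensities must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise DimensionError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def full_scale(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass(frozen=True)
class Spectrum:
    """DC-centered 2D discrete Fourier transform of a hologram."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        if v.ndim != 2:
            raise DimensionError(f"spectrum must be 2D, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def dc_index(self) -> tuple[int, int]:
        return (self.shape[0] // 2, self.shape[1] // 2)


@dataclass(frozen=True)
class WindowGeometry:
    """Maximum windowing square around a sideband peak (Fig.-style a,b,c,d)."""

    shape: tuple[int, int]
    peak: tuple[int, int]
    a: int
    b: int
    c: int
    d: int
    Rm: int


@dataclass(frozen=True)
class WindowPlan:
    """A reproducible set of window centers for sideband extraction."""

    geometry: WindowGeometry
    SW: int
    NR: int
    centers: tuple[tuple[int, int], ...]
    seed: int

    def to_dict(self) -> dict:
        g = self.geometry
        return {
            "shape": list(g.shape),
            "peak": list(g.peak),
            "a": g.a,
            "b": g.b,
            "c": g.c,
            "d": g.d,
            "Rm": g.Rm,
            "SW": self.SW,
            "NR": self.NR,
            "seed": self.seed,
            "centers": [list(c) for c in self.centers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WindowPlan":
        geom = WindowGeometry(
            shape=tuple(d["shape"]),
            peak=tuple(d["peak"]),
            a=d["a"],
            b=d["b"],
            c=d["c"],
            d=d["d"],
            Rm=d["Rm"],
        )
        return cls(
            geometry=geom,
            SW=d["SW"],
            NR=d["NR"],
            centers=tuple(tuple(c) for c in d["centers"]),
            seed=d["seed"],
        )


def compute_spectrum(h: Hologram | np.ndarray) -> Spectrum:
    """DC-centered 2D DFT of a hologram.

    Uses the unnormalized forward transform, so a constant image of value
    ``v`` maps to a single DC bin of magnitude ``v * H * W``.
    """
    px = h.pixels if isinstance(h, Hologram) else np.asarray(h, dtype=float)
    if px.ndim != 2 or min(px.shape) < 8:
        raise DimensionError(
            f"expected a 2D grid of at least 8x8 pixels, got shape {np.shape(px)}"
        )
    return Spectrum(np.fft.fftshift(np.fft.fft2(px)))


def invert_spectrum(s: Spectrum) -> np.ndarray:
    """Inverse of :func:`compute_spectrum`; returns the complex field."""
    return np.fft.ifft2(np.fft.ifftshift(s.values))


def locate_sideband_peak(s: Spectrum, dc_exclusion_radius: int = 8) -> tuple[int, int]:
    """Coordinate of the strongest bin on the positive-horizontal half-plane.

    Bins within ``dc_exclusion_radius`` of DC (Euclidean, inclusive) and bins
    with horizontal frequency <= 0 are excluded. Ties break to the first bin
    in row-major scan order.
    """
    if dc_exclusion_radius < 1:
        raise GeometryError("dc_exclusion_radius must be >= 1")
    mag = np.abs(s.values)
    cy, cx = s.dc_index
    rows = np.arange(s.shape[0])[:, None] - cy
    cols = np.arange(s.shape[1])[None, :] - cx
    candidate = (rows**2 + cols**2 > dc_exclusion_radius**2) & (cols > 0)
    if not np.any(candidate & (mag > 0)):
        raise NoSidebandError("no nonzero spectral bin outside the DC exclusion disk")
    masked = np.where(candidate, mag, -1.0)
    flat = int(np.argmax(masked))  # argmax is row-major-first on ties
    return (flat // s.shape[1], flat % s.shape[1])


def compute_window_geometry(
    s_shape: tuple[int, int], peak: tuple[int, int]
) -> WindowGeometry:
    """Maximum windowing square for a sideband peak.

    ``a`` is half the horizontal peak-to-DC distance, ``b`` the horizontal
    distance to the nearer lateral edge, ``c``/``d`` the vertical distances
    to the top and bottom resolution limits; ``Rm = 2*min(a,b,c,d)`` (even
    by construction).
    """
    H, W = s_shape
    pr, pc = peak
    if not (0 <= pr < H and 0 <= pc < W):
        raise GeometryError(f"peak {peak} lies outside a {H}x{W} grid")
    cx = W // 2
    horiz = abs(pc - cx)
    a = horiz // 2
    if a == 0:
        raise GeometryError(
            "sideband peak is on (or adjacent to) the DC column: a = 0 admits no window"
        )
    b = min(pc, W - 1 - pc)
    c = pr
    d = H - pr
    Rm = 2 * min(a, b, c, d)
    if Rm <= 0:
        raise GeometryError(f"degenerate window geometry at peak {peak}: Rm = {Rm}")
    return WindowGeometry(shape=(H, W), peak=(pr, pc), a=a, b=b, c=c, d=d, Rm=Rm)


def default_window_size(g: WindowGeometry) -> int:
    """Default window side: 2/3 of Rm, snapped down to an odd integer.

    An odd side gives the window a unique central pixel, so "centered on"
    is unambiguous. Raises when no such side satisfies Rm/2 < SW < Rm.
    """
    sw = (2 * g.Rm) // 3
    if sw % 2 == 0:
        sw -= 1
    if not (2 * sw > g.Rm and sw < g.Rm):
        raise WindowSizeError(
            f"Rm = {g.Rm} admits no odd window side in (Rm/2, Rm); "
            "increase the carrier frequency or the grid size"
        )
    return sw


def _validate_sw(Rm: int, SW: int) -> None:
    if not (2 * SW > Rm and SW < Rm):
        raise WindowSizeError(
            f"window side SW = {SW} violates Rm/2 < SW < Rm with Rm = {Rm}"
        )


def sample_window_centers(
    g: WindowGeometry, SW: int, NR: int, seed: int
) -> WindowPlan:
    """Sample ``NR`` distinct window centers inside the eligible square.

    The first center is always the sideband peak; the remaining ``NR - 1``
    are drawn uniformly without replacement from the square of centers whose
    SW-sided windows fit inside the maximum square, i.e. offsets within
    ``±(Rm - SW)//2`` of the peak on both axes.
    """
    _validate_sw(g.Rm, SW)
    if NR < 1:
        raise SamplingError(f"NR must be >= 1, got {NR}")
    off = (g.Rm - SW) // 2
    side = 2 * off + 1
    n_eligible = side * side
    if NR > n_eligible:
        raise SamplingError(
            f"NR = {NR} exceeds the {side}x{side} = {n_eligible} eligible centers"
        )
    pr, pc = g.peak
    centers = [(pr, pc)]
    if NR > 1:
        offsets = [
            (dr, dc)
            for dr in range(-off, off + 1)
            for dc in range(-off, off + 1)
            if (dr, dc) != (0, 0)
        ]
        rng = np.random.default_rng(seed)
        picks = rng.choice(len(offsets), size=NR - 1, replace=False)
        centers.extend((pr + offsets[i][0], pc + offsets[i][1]) for i in picks)
    return WindowPlan(geometry=g, SW=SW, NR=NR, centers=tuple(centers), seed=seed)


def extract_windowed_sideband(
    s: Spectrum, center: tuple[int, int], SW: int
) -> Spectrum:
    """Copy an SW-sided square around ``center`` to a DC-centered position.

    Returns a full-size spectrum, zero outside the copied square, with the
    square translated so that ``center`` lands on the DC bin — recentering
    the window removes the fringe carrier. The same ``(center, SW)`` must be
    applied to the paired reference spectrum so residual carrier offsets
    cancel in the phase difference.
    """
    if SW < 1 or SW % 2 == 0:
        raise WindowSizeError(f"window side must be a positive odd integer, got {SW}")
    H, W = s.shape
    cr, cc = center
    half = SW // 2
    if cr - half < 0 or cr + half >= H or cc - half < 0 or cc + half >= W:
        raise BoundsError(
            f"{SW}x{SW} window at center {center} overruns the {H}x{W} grid"
        )
    block = s.values[cr - half : cr + half + 1, cc - half : cc + half + 1]
    out = np.zeros_like(s.values)
    dy, dx = s.dc_index
    if dy - half < 0 or dy + half >= H or dx - half < 0 or dx + half >= W:
        raise BoundsError(f"{SW}x{SW} window does not fit around DC on a {H}x{W} grid")
    out[dy - half : dy + half + 1, dx - half : dx + half + 1] = block
    return Spectrum(out)
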