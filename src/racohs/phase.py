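"""Wrapped-phase retrieval, Goldstein branch-cut unwrapping, and height maps.

The windowed sideband, inverse-transformed, is a complex field whose
argument is the wrapped optical phase. The object-minus-reference phase
difference is proportional to optical path length, hence to object height:

    dphi = K * dn * h,      K = 2*pi / lambda,   dn = n_object - n_medium

so ``h = dphi / (K * dn)`` converts phase (radians) to height (micrometers).

Unwrapping follows Goldstein's branch-cut strategy: residues (per-plaquette
winding charges of the wrapped gradient field) are paired with opposite
charges or grounded to the border by short cuts; integration of wrapped
gradients then flood-fills the grid without crossing any cut, making the
result path-independent. Pixels walled off by cuts are filled from their
nearest unwrapped neighbour and flagged so downstream averaging can
down-weight them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import DimensionError, ParameterError, UnwrapError

__all__ = [
    "OpticalParameters",
    "WrappedPhaseMap",
    "UnwrappedPhaseMap",
    "ResidueGrid",
    "HeightMap",
    "wrap_phase",
    "reconstruct_wrapped_phase",
    "wrapped_difference",
    "compute_residues",
    "goldstein_unwrap",
    "phase_to_height",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class OpticalParameters:
    """Wavelength, refractive indices and sampling of the imaging system.

    All lengths are micrometers. ``pixel_pitch`` is the pitch at the object
    plane (sensor pitch divided by magnification).
    """

    wavelength: float = 0.532
    n_object: float = 1.42
    n_medium: float = 1.34
    pixel_pitch: float = 0.055

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ParameterError("wavelength must be positive (micrometers)")
        if self.pixel_pitch <= 0:
            raise ParameterError("pixel_pitch must be positive (micrometers)")
        if self.delta_n == 0:
            raise ParameterError(
                "refractive-index contrast is zero: n_object must differ from n_medium"
            )

    @property
    def wavenumber(self) -> float:
        """K = 2*pi / lambda, radians per micrometer."""
        return TWO_PI / self.wavelength

    @property
    def delta_n(self) -> float:
        return self.n_object - self.n_medium


def wrap_phase(x: np.ndarray | float) -> np.ndarray:
    """Wrap radians into the principal interval [-pi, pi)."""
    return (np.asarray(x, dtype=float) + np.pi) % TWO_PI - np.pi


@dataclass(frozen=True)
class WrappedPhaseMap:
    """Per-pixel phase in [-pi, pi)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise DimensionError(f"phase map must be 2D, got shape {v.shape}")
        object.__setattr__(self, "values", wrap_phase(v))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class UnwrappedPhaseMap:
    """Continuous phase surface plus a mask of fallback-filled pixels."""

    values: np.ndarray
    unreliable_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ResidueGrid:
    """Integer winding charges on 2x2 plaquettes, each in {-1, 0, +1}."""

    charges: np.ndarray

    @property
    def total_charge(self) -> int:
        return int(self.charges.sum())


@dataclass(frozen=True)
class HeightMap:
    """Per-pixel object height in micrometers."""

    values: np.ndarray
    pixel_pitch: float = 0.055

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def reconstruct_wrapped_phase(ws) -> WrappedPhaseMap:
    """Inverse-transform a windowed spectrum and take the per-pixel argument.

    Accepts a :class:`~racohs.windowing.Spectrum` (or bare complex field)
    and returns arctan2(Im, Re) wrapped to [-pi, pi).
    """
    from .windowing import Spectrum, invert_spectrum

    if isinstance(ws, Spectrum):
        field_ = invert_spectrum(ws)
    else:
        field_ = np.asarray(ws, dtype=complex)
    if not np.any(field_ != 0):
        raise UnwrapError("all-zero field has undefined phase")
    return WrappedPhaseMap(np.arctan2(field_.imag, field_.real))


def wrapped_difference(obj: WrappedPhaseMap, ref: WrappedPhaseMap) -> WrappedPhaseMap:
    """Object-minus-reference phase, rewrapped to [-pi, pi)."""
    if obj.shape != ref.shape:
        raise DimensionError(
            f"phase maps differ in shape: {obj.shape} vs {ref.shape}"
        )
    return WrappedPhaseMap(wrap_phase(obj.values - ref.values))


def compute_residues(w: WrappedPhaseMap) -> ResidueGrid:
    """Winding charge of each 2x2 plaquette of the wrapped phase.

    Sums the four wrapped differences around the loop
    (i,j)->(i,j+1)->(i+1,j+1)->(i+1,j)->(i,j) and divides by 2*pi. Smooth
    fields (all wrapped gradients < pi in magnitude) have zero everywhere.
    """
    v = w.values
    if v.shape[0] < 2 or v.shape[1] < 2:
        raise DimensionError("residues need at least a 2x2 grid")
    d_right = wrap_phase(v[:-1, 1:] - v[:-1, :-1])  # (i,j) -> (i,j+1)
    d_down = wrap_phase(v[1:, 1:] - v[:-1, 1:])  # (i,j+1) -> (i+1,j+1)
    d_left = wrap_phase(v[1:, :-1] - v[1:, 1:])  # (i+1,j+1) -> (i+1,j)
    d_up = wrap_phase(v[:-1, :-1] - v[1:, :-1])  # (i+1,j) -> (i,j)
    loop = d_right + d_down + d_left + d_up
    charges = np.rint(loop / TWO_PI).astype(int)
    return ResidueGrid(charges)


def _bresenham(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """8-connected pixel chain from (r0,c0) to (r1,c1), inclusive."""
    pts = []
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    r, c = r0, c0
    while True:
        pts.append((r, c))
        if r == r1 and c == c1:
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return pts


def _place_branch_cuts(charges: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Greedy growing-radius pairing of residues; returns the cut-pixel mask.

    Each unbalanced residue searches boxes of radius 1, 2, 4, ... for the
    nearest opposite-charge unbalanced residue; if the grid border is at
    least as close, the residue is grounded to the border instead. Cuts are
    rasterized as 8-connected pixel chains, which 4-connected integration
    paths cannot cross.
    """
    H, W = shape
    cut = np.zeros(shape, dtype=bool)
    active = charges.copy()
    locs = np.argwhere(active != 0)
    # residue at plaquette (i, j) sits at the shared corner of pixels
    # (i..i+1, j..j+1); pixel (i, j) anchors its cuts
    for i, j in locs:
        if active[i, j] == 0:
            continue
        q = active[i, j]
        radius = 1
        max_radius = max(H, W)
        balanced = False
        while not balanced and radius <= max_radius:
            border_dist = min(i + 1, j + 1, H - 1 - i, W - 1 - j)
            if border_dist <= radius:
                # ground to nearest border
                if border_dist == i + 1:
                    tr, tc = 0, j
                elif border_dist == j + 1:
                    tr, tc = i, 0
                elif border_dist == H - 1 - i:
                    tr, tc = H - 1, j
                else:
                    tr, tc = i, W - 1
                for p in _bresenham(i, j, tr, tc):
                    cut[p] = True
                active[i, j] = 0
                balanced = True
                break
            r0, r1 = max(0, i - radius), min(active.shape[0] - 1, i + radius)
            c0, c1 = max(0, j - radius), min(active.shape[1] - 1, j + radius)
            box = active[r0 : r1 + 1, c0 : c1 + 1]
            partners = np.argwhere(box == -q)
            if partners.size:
                # nearest opposite charge (Chebyshev, then row-major)
                dist = np.maximum(
                    np.abs(partners[:, 0] + r0 - i), np.abs(partners[:, 1] + c0 - j)
                )
                k = int(np.argmin(dist))
                pi_, pj = partners[k, 0] + r0, partners[k, 1] + c0
                for p in _bresenham(i, j, pi_, pj):
                    cut[p] = True
                active[i, j] = 0
                active[pi_, pj] = 0
                balanced = True
                break
            radius *= 2
        if not balanced:
            # pathological: no partner anywhere; ground to border
            for p in _bresenham(i, j, 0, j):
                cut[p] = True
            active[i, j] = 0
    return cut


def _flood_integrate(
    w: np.ndarray, blocked: np.ndarray, seed: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Layered 4-connected flood fill integrating wrapped gradients.

    Returns (values, done) where ``done`` marks pixels reached without
    crossing a blocked pixel. Vectorized: each sweep admits the whole
    frontier at once, so the loop count is bounded by the grid diameter.
    """
    H, W = w.shape
    values = np.zeros_like(w)
    done = np.zeros((H, W), dtype=bool)
    sr, sc = seed
    values[sr, sc] = w[sr, sc]
    done[sr, sc] = True
    while True:
        grew = False
        for shift_ax, shift_by in ((0, 1), (0, -1), (1, 1), (1, -1)):
            src_done = np.roll(done, shift_by, axis=shift_ax)
            src_vals = np.roll(values, shift_by, axis=shift_ax)
            src_w = np.roll(w, shift_by, axis=shift_ax)
            # roll wraps around the grid edge; sever those links
            if shift_ax == 0:
                if shift_by == 1:
                    src_done[0, :] = False
                else:
                    src_done[-1, :] = False
            else:
                if shift_by == 1:
                    src_done[:, 0] = False
                else:
                    src_done[:, -1] = False
            new = src_done & ~done & ~blocked
            if np.any(new):
                values[new] = src_vals[new] + wrap_phase(w[new] - src_w[new])
                done |= new
                grew = True
        if not grew:
            break
    return values, done


def goldstein_unwrap(
    w: WrappedPhaseMap, seed: Optional[tuple[int, int]] = None
) -> UnwrappedPhaseMap:
    """Goldstein branch-cut unwrapping of a wrapped phase map.

    Residues are computed, paired by greedy growing-radius search (with the
    border as an opposite-charge sink), and rasterized into a cut mask;
    wrapped gradients are then integrated by flood fill from ``seed``
    (default: grid center) without crossing cuts. Pixels unreachable under
    the cuts — the cut pixels themselves and any region they enclose — are
    filled from their nearest unwrapped neighbour and flagged in
    ``unreliable_mask``. The output is defined up to one global multiple of
    2*pi; rewrapping it reproduces the input exactly.
    """
    v = w.values
    H, W = v.shape
    if H < 2 or W < 2:
        raise DimensionError("unwrapping needs at least a 2x2 grid")
    charges = compute_residues(w).charges
    if np.any(charges != 0):
        cut = _place_branch_cuts(charges, (H, W))
    else:
        cut = np.zeros((H, W), dtype=bool)

    if seed is None:
        seed = (H // 2, W // 2)
    if cut[seed]:
        free = np.argwhere(~cut)
        if free.size == 0:
            raise UnwrapError("branch cuts saturate the grid: every pixel is cut")
        d = np.abs(free[:, 0] - seed[0]) + np.abs(free[:, 1] - seed[1])
        seed = tuple(free[int(np.argmin(d))])

    values, done = _flood_integrate(v, cut, seed)
    if not np.any(done):
        raise UnwrapError("flood fill could not unwrap any pixel")

    unreliable = ~done
    if np.any(unreliable):
        # second pass: fill remaining pixels from nearest unwrapped
        # neighbours, still via wrapped gradients (keeps rewrap consistency)
        fill_vals, fill_done = _flood_integrate_from(v, done, values)
        values = np.where(done, values, fill_vals)
        if not np.all(fill_done | done):
            raise UnwrapError("isolated pixels remain after fallback fill")
    return UnwrappedPhaseMap(values=values, unreliable_mask=unreliable)


def _flood_integrate_from(
    w: np.ndarray, done0: np.ndarray, values0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Grow an existing unwrapped region over the rest of the grid."""
    values = values0.copy()
    done = done0.copy()
    while True:
        grew = False
        for shift_ax, shift_by in ((0, 1), (0, -1), (1, 1), (1, -1)):
            src_done = np.roll(done, shift_by, axis=shift_ax)
            src_vals = np.roll(values, shift_by, axis=shift_ax)
            src_w = np.roll(w, shift_by, axis=shift_ax)
            if shift_ax == 0:
                if shift_by == 1:
                    src_done[0, :] = False
                else:
                    src_done[-1, :] = False
            else:
                if shift_by == 1:
                    src_done[:, 0] = False
                else:
                    src_done[:, -1] = False
            new = src_done & ~done
            if np.any(new):
                values[new] = src_vals[new] + wrap_phase(w[new] - src_w[new])
                done |= new
                grew = True
        if not grew:
            break
    return values, done


def phase_to_height(
    dphi: UnwrappedPhaseMap | np.ndarray, p: OpticalParameters
) -> HeightMap:
    """Convert an unwrapped phase difference to height: h = dphi / (K*dn)."""
    vals = dphi.values if isinstance(dphi, UnwrappedPhaseMap) else np.asarray(dphi, float)
    scale = p.wavenumber * p.delta_n
    if scale == 0:
        raise ParameterError("K * delta_n is zero; cannot convert phase to height")
    return HeightMap(values=vals / scale, pixel_pitch=p.pixel_pitch)
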