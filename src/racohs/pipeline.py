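"""End-to-end reconstruction: single-sideband baseline and RaCoHS averaging.

The conventional reconstruction windows one square around the sideband
peak, extracts it from both spectra, forms the object-minus-reference
wrapped phase difference, unwraps it once, and converts phase to height.

RaCoHS repeats that chain for ``NR`` windows of identical size whose
centers are drawn at random inside the eligible square (the peak always
included), and averages the resulting height maps pixelwise:

    h_racohs = (1 / NR) * sum_i  dphi_i / (K * dn)

Noise leaked from the broad DC spectrum into a window depends on where the
window sits, so it decorrelates across centers and averages down, while
the object's phase content — carried coherently by every window — is
preserved. The Gaussian-filter baseline, by contrast, buys noise reduction
by attenuating high spatial frequencies of the height map itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy import ndimage

from .exceptions import DimensionError, LevelingError
from .phase import (
    HeightMap,
    OpticalParameters,
    TWO_PI,
    goldstein_unwrap,
    phase_to_height,
    reconstruct_wrapped_phase,
    wrapped_difference,
)
from .windowing import (
    Hologram,
    Spectrum,
    WindowPlan,
    compute_spectrum,
    compute_window_geometry,
    default_window_size,
    extract_windowed_sideband,
    invert_spectrum,
    locate_sideband_peak,
    sample_window_centers,
)

__all__ = [
    "Method",
    "ReconstructionResult",
    "reconstruct_conventional",
    "reconstruct_racohs",
    "gaussian_baseline",
    "level_background",
]


class Method(str, Enum):
    CONVENTIONAL = "conventional"
    RACOHS = "racohs"
    GAUSSIAN = "gaussian_baseline"


@dataclass(frozen=True)
class ReconstructionResult:
    height: HeightMap
    plan: WindowPlan
    method: Method
    per_center_heights: Optional[tuple[np.ndarray, ...]] = None


def _height_for_center(
    ref_spec: Spectrum,
    obj_spec: Spectrum,
    center: tuple[int, int],
    SW: int,
    p: OpticalParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """One term of the RaCoHS sum: height map + unreliable mask for a center.

    The identical (center, SW) is applied to both spectra so the carrier
    ramp introduced by window recentering cancels exactly in the phase
    difference. The unwrap is seeded at the pixel of maximum object-field
    magnitude (highest SNR). The unwrapped difference is snapped to the
    2*pi branch that puts its median near zero, fixing the arbitrary
    global 2*pi multiple before maps from different centers are averaged.
    """
    ws_obj = extract_windowed_sideband(obj_spec, center, SW)
    ws_ref = extract_windowed_sideband(ref_spec, center, SW)
    field_obj = invert_spectrum(ws_obj)
    phi_obj = reconstruct_wrapped_phase(field_obj)
    phi_ref = reconstruct_wrapped_phase(invert_spectrum(ws_ref))
    dphi_w = wrapped_difference(phi_obj, phi_ref)
    mag = np.abs(field_obj)
    seed = np.unravel_index(int(np.argmax(mag)), mag.shape)
    unwrapped = goldstein_unwrap(dphi_w, seed=seed)
    vals = unwrapped.values - TWO_PI * np.round(np.median(unwrapped.values) / TWO_PI)
    h = phase_to_height(vals, p)
    return h.values, unwrapped.unreliable_mask


def _plan_for(
    obj_spec: Spectrum,
    NR: int,
    seed: int,
    SW: Optional[int],
    dc_exclusion_radius: int,
) -> WindowPlan:
    peak = locate_sideband_peak(obj_spec, dc_exclusion_radius=dc_exclusion_radius)
    geom = compute_window_geometry(obj_spec.shape, peak)
    if SW is None:
        SW = default_window_size(geom)
    return sample_window_centers(geom, SW, NR, seed)


def reconstruct_racohs(
    ref: Hologram,
    obj: Hologram,
    p: OpticalParameters,
    NR: int = 20,
    seed: int = 0,
    SW: Optional[int] = None,
    dc_exclusion_radius: int = 8,
    level: bool = True,
    keep_per_center: bool = False,
) -> ReconstructionResult:
    """RaCoHS reconstruction: mean height over NR randomly-centred windows.

    Per-center pixels flagged unreliable by the unwrapper are excluded from
    the mean at those pixels (mask-aware mean); a pixel unreliable in every
    term falls back to the plain mean. With ``NR = 1`` the plan holds only
    the sideband peak and the result is bit-identical to the conventional
    reconstruction at the same SW.
    """
    if ref.shape != obj.shape:
        raise DimensionError(
            f"reference and object holograms differ in shape: {ref.shape} vs {obj.shape}"
        )
    ref_spec = compute_spectrum(ref)
    obj_spec = compute_spectrum(obj)
    plan = _plan_for(obj_spec, NR, seed, SW, dc_exclusion_radius)

    heights = np.empty((plan.NR,) + obj.shape)
    good = np.empty((plan.NR,) + obj.shape, dtype=bool)
    for i, center in enumerate(plan.centers):
        h_i, bad_i = _height_for_center(ref_spec, obj_spec, center, plan.SW, p)
        heights[i] = h_i
        good[i] = ~bad_i
    n_good = good.sum(axis=0)
    masked_sum = np.where(good, heights, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_good > 0, masked_sum / np.maximum(n_good, 1),
                        heights.mean(axis=0))
    hmap = HeightMap(values=mean, pixel_pitch=p.pixel_pitch)
    if level:
        hmap = level_background(hmap)
    return ReconstructionResult(
        height=hmap,
        plan=plan,
        method=Method.RACOHS if NR > 1 else Method.CONVENTIONAL,
        per_center_heights=tuple(heights) if keep_per_center else None,
    )


def reconstruct_conventional(
    ref: Hologram,
    obj: Hologram,
    p: OpticalParameters,
    SW: Optional[int] = None,
    dc_exclusion_radius: int = 8,
    level: bool = True,
) -> ReconstructionResult:
    """Single-sideband baseline: one window, centred on the sideband peak."""
    res = reconstruct_racohs(
        ref, obj, p, NR=1, seed=0, SW=SW,
        dc_exclusion_radius=dc_exclusion_radius, level=level,
    )
    return ReconstructionResult(
        height=res.height, plan=res.plan, method=Method.CONVENTIONAL,
        per_center_heights=res.per_center_heights,
    )


def gaussian_baseline(r: ReconstructionResult, sigma: float = 2.0) -> ReconstructionResult:
    """Gaussian low-pass of a reconstructed height map (reflective edges)."""
    if sigma <= 0:
        raise DimensionError(f"sigma must be positive, got {sigma}")
    smoothed = ndimage.gaussian_filter(r.height.values, sigma=sigma, mode="reflect")
    return ReconstructionResult(
        height=HeightMap(values=smoothed, pixel_pitch=r.height.pixel_pitch),
        plan=r.plan,
        method=Method.GAUSSIAN,
    )


def level_background(
    h: HeightMap, background_mask: Optional[np.ndarray] = None
) -> HeightMap:
    """Remove the substrate tilt: subtract the LS plane fit to background.

    The slide is never perfectly level at micrometer scale, so height is
    meaningful only relative to the background plane. Default background:
    pixels at or below the 25th height percentile. After plane removal the
    background median is subtracted so it sits at zero.
    """
    v = h.values
    if background_mask is None:
        background_mask = v <= np.percentile(v, 25)
    else:
        background_mask = np.asarray(background_mask, dtype=bool)
        if background_mask.shape != v.shape:
            raise DimensionError("background mask shape differs from height map")
    if not np.any(background_mask):
        raise LevelingError("background mask selects no pixels")
    rows, cols = np.nonzero(background_mask)
    A = np.column_stack([cols, rows, np.ones_like(rows)]).astype(float)
    coef, *_ = np.linalg.lstsq(A, v[rows, cols], rcond=None)
    yy, xx = np.mgrid[0 : v.shape[0], 0 : v.shape[1]]
    plane = coef[0] * xx + coef[1] * yy + coef[2]
    leveled = v - plane
    leveled = leveled - np.median(leveled[background_mask])
    return HeightMap(values=leveled, pixel_pitch=h.pixel_pitch)
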