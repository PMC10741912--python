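"""Synthetic off-axis hologram pairs with known ground-truth height.

The forward model is the off-axis interference intensity

    I(x, y) = A_R^2 + A_O^2 + 2 A_R A_O cos(2*pi*(fx*x + fy*y) + phi(x, y))

with a plane-wave fringe carrier ``(fx, fy)`` in cycles per pixel and an
object phase ``phi = K * dn * h`` imprinted by a transparent phantom of
height ``h`` micrometers. A shared Gaussian beam-amplitude envelope makes
the illumination nonuniform, which is what spreads the DC term over a broad
band of low frequencies in the Fourier domain (the noise source the
random-center averaging is designed to decorrelate). Additive Gaussian
camera noise, clipping to full scale, and quantization to the sensor bit
depth complete the model. The reference hologram is the same field with
``phi = 0`` and an independent noise draw.

Phantoms
--------
``sphere_chord_phantom``
    Transmissive bead model: the optical path integrates through the whole
    sphere, so the ideal profile is the chord length h = 2*sqrt(r^2 - rho^2)
    and its maximum equals the bead diameter.
``rbc_biconcave_phantom``
    Rotationally symmetric discocyte (central dimple, raised annular rim),
    an Evans–Fung-style polynomial thickness profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .exceptions import DimensionError, GeometryError, ParameterError
from .phase import HeightMap, OpticalParameters
from .windowing import Hologram, HologramRole

__all__ = [
    "Phantom",
    "PhantomKind",
    "SimulationConfig",
    "FringeSpacingWarning",
    "sphere_chord_phantom",
    "rbc_biconcave_phantom",
    "flat_phantom",
    "simulate_hologram_pair",
    "fringe_spacing_check",
]


class PhantomKind(str, Enum):
    SPHERE_CHORD = "sphere_chord"
    RBC_BICONCAVE = "rbc_biconcave"
    FLAT = "flat"
    CUSTOM = "custom"


class FringeSpacingWarning(UserWarning):
    """Carrier so low that the windowing range Rm degrades."""


@dataclass(frozen=True)
class Phantom:
    """Ground-truth height profile used to drive the simulator."""

    height: HeightMap
    kind: PhantomKind = PhantomKind.CUSTOM

    def __post_init__(self) -> None:
        v = self.height.values
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise GeometryError("phantom heights must be finite and nonnegative")


@dataclass(frozen=True)
class SimulationConfig:
    """Optical, carrier, envelope, noise and sensor settings for a run.

    ``carrier`` is in cycles per pixel; 0.1875 puts the sideband peak at
    3/8 of the Nyquist range, leaving the largest usable windowing square
    for horizontal fringes. ``beam_envelope_sigma`` (pixels) controls the
    Gaussian illumination falloff (``None`` = uniform beam);
    ``noise_sigma`` is the camera-noise standard deviation as a fraction
    of full scale.
    """

    optics: OpticalParameters = field(default_factory=OpticalParameters)
    carrier: tuple[float, float] = (0.1875, 0.0)
    beam_envelope_sigma: Optional[float] = None
    noise_sigma: float = 0.02
    bit_depth: int = 16
    seed: int = 0
    grid: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")
        if len(self.grid) != 2 or min(self.grid) < 8:
            raise DimensionError(f"grid must be at least 8x8, got {self.grid}")

    @property
    def full_scale(self) -> int:
        return (1 << self.bit_depth) - 1


def flat_phantom(grid: tuple[int, int], pitch: float = 0.055) -> Phantom:
    """Zero-height phantom (object slide with nothing on it)."""
    return Phantom(
        height=HeightMap(values=np.zeros(grid), pixel_pitch=pitch),
        kind=PhantomKind.FLAT,
    )


def sphere_chord_phantom(
    diameter: float, grid: tuple[int, int], pitch: float = 0.055
) -> Phantom:
    """Transmissive microsphere: chord-length profile, peak = diameter.

    h(rho) = 2*sqrt(r^2 - rho^2) for rho <= r, else 0, with r = diameter/2.
    The bead is centred in the field and must fit inside it.
    """
    if diameter <= 0:
        raise GeometryError("diameter must be positive")
    H, W = grid
    r = diameter / 2.0
    if 2 * r >= min(H, W) * pitch:
        raise GeometryError(
            f"sphere of diameter {diameter} um does not fit a "
            f"{H}x{W} field at pitch {pitch} um"
        )
    yy, xx = np.mgrid[0:H, 0:W]
    rho2 = ((xx - (W - 1) / 2.0) * pitch) ** 2 + ((yy - (H - 1) / 2.0) * pitch) ** 2
    h = 2.0 * np.sqrt(np.clip(r * r - rho2, 0.0, None))
    return Phantom(
        height=HeightMap(values=h, pixel_pitch=pitch), kind=PhantomKind.SPHERE_CHORD
    )


# Evans-Fung discocyte thickness coefficients (normalized radius), scaled
# below so the rim maximum hits the requested max_height exactly.
_RBC_C0, _RBC_C2, _RBC_C4 = 0.81, 7.83, -4.39


def rbc_biconcave_phantom(
    diameter: float = 7.8,
    max_height: float = 2.4,
    grid: tuple[int, int] = (512, 512),
    pitch: float = 0.055,
) -> Phantom:
    """Biconcave red-blood-cell phantom: central dimple, annular rim.

    Thickness follows sqrt(1 - u^2) * (C0 + C2 u^2 + C4 u^4) in normalized
    radius u = 2*rho/diameter, rescaled so the rim maximum equals
    ``max_height``; zero outside the disk.
    """
    if diameter <= 0 or max_height <= 0:
        raise GeometryError("diameter and max_height must be positive")
    H, W = grid
    yy, xx = np.mgrid[0:H, 0:W]
    rho = np.hypot((xx - (W - 1) / 2.0) * pitch, (yy - (H - 1) / 2.0) * pitch)
    u2 = np.clip((2.0 * rho / diameter) ** 2, 0.0, 1.0)
    profile = np.sqrt(1.0 - u2) * (_RBC_C0 + _RBC_C2 * u2 + _RBC_C4 * u2**2)
    profile[rho > diameter / 2.0] = 0.0
    # analytic rim maximum of the same polynomial on a fine radial grid
    uf2 = np.linspace(0.0, 1.0, 20001)
    peak = np.max(np.sqrt(1.0 - uf2) * (_RBC_C0 + _RBC_C2 * uf2 + _RBC_C4 * uf2**2))
    h = np.clip(profile, 0.0, None) * (max_height / peak)
    return Phantom(
        height=HeightMap(values=h, pixel_pitch=pitch), kind=PhantomKind.RBC_BICONCAVE
    )


def fringe_spacing_check(cfg: SimulationConfig) -> float:
    """Return |carrier| (cycles/pixel); warn when the sideband sits too low.

    A carrier below 1/8 of the Nyquist range leaves the sideband peak so
    close to DC that the maximum windowing square Rm collapses.
    """
    mag = float(np.hypot(*cfg.carrier))
    if 0 < mag < 0.5 / 8.0:
        warnings.warn(
            f"carrier magnitude {mag:.4f} cycles/px is below 1/8 of the "
            "Nyquist range; the windowing range Rm will be severely limited",
            FringeSpacingWarning,
            stacklevel=2,
        )
    return mag


def _beam_amplitude(cfg: SimulationConfig) -> np.ndarray:
    H, W = cfg.grid
    if cfg.beam_envelope_sigma is None:
        return np.ones((H, W))
    s = float(cfg.beam_envelope_sigma)
    if s <= 0:
        raise ParameterError("beam_envelope_sigma must be positive or None")
    yy, xx = np.mgrid[0:H, 0:W]
    r2 = (xx - (W - 1) / 2.0) ** 2 + (yy - (H - 1) / 2.0) ** 2
    return np.exp(-r2 / (2.0 * s * s))


def simulate_hologram_pair(
    ph: Phantom, cfg: SimulationConfig
) -> tuple[Hologram, Hologram]:
    """Simulate a (reference, object) hologram pair for a phantom.

    The object-beam phase is phi = K * dn * h; the reference hologram is
    generated with phi = 0 under the same carrier and envelope. Both get
    independent seeded Gaussian noise, clipping to [0, full scale], and
    quantization to the configured bit depth.
    """
    if ph.height.shape != tuple(cfg.grid):
        raise DimensionError(
            f"phantom grid {ph.height.shape} differs from config grid {cfg.grid}"
        )
    fx, fy = cfg.carrier
    if np.hypot(fx, fy) >= 0.5:
        raise ParameterError(
            f"carrier {cfg.carrier} meets or exceeds Nyquist (0.5 cycles/px): "
            "the sideband would alias"
        )
    fringe_spacing_check(cfg)
    H, W = cfg.grid
    yy, xx = np.mgrid[0:H, 0:W]
    carrier_phase = 2.0 * np.pi * (fx * xx + fy * yy)
    phi = cfg.optics.wavenumber * cfg.optics.delta_n * ph.height.values
    amp = _beam_amplitude(cfg)
    a2 = amp * amp

    rng = np.random.default_rng(cfg.seed)
    full = cfg.full_scale
    scale = full / 4.0  # peak intensity of 2 A^2 (1 + cos) with A <= 1

    holos = []
    for role, phase in (
        (HologramRole.REFERENCE, carrier_phase),
        (HologramRole.OBJECT, carrier_phase + phi),
    ):
        intensity = 2.0 * a2 * (1.0 + np.cos(phase)) * scale
        if cfg.noise_sigma > 0:
            intensity = intensity + rng.normal(0.0, cfg.noise_sigma * full, (H, W))
        intensity = np.clip(intensity, 0.0, full)
        quantized = np.rint(intensity)
        holos.append(Hologram(pixels=quantized, role=role, bit_depth=cfg.bit_depth))
    return holos[0], holos[1]
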