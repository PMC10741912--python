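"""Fidelity metrics (SSIM, MSE, background RMS) and the comparison bench.

SSIM follows the original formulation: local statistics over a sliding
uniform window (default 7x7), stabilizers C1 = (K1*L)^2, C2 = (K2*L)^2
with K1 = 0.01, K2 = 0.03 and L the data range, sample (n-1) covariance
normalization, and the mean of the local index map over valid positions.

``compare_methods`` runs each reconstruction method over a set of
simulated hologram pairs and scores every output against the ideal
phantom profile, producing per-sample rows and per-method averages — the
synthetic analogue of a bead-by-bead comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DimensionError, LevelingError, ParameterError
from .phase import HeightMap, OpticalParameters
from .pipeline import (
    Method,
    gaussian_baseline,
    level_background,
    reconstruct_conventional,
    reconstruct_racohs,
)
from .simulate import Phantom, SimulationConfig, simulate_hologram_pair, sphere_chord_phantom
from .windowing import Hologram

__all__ = [
    "MetricReport",
    "mse",
    "ssim",
    "background_rms",
    "compare_methods",
    "bench_sphere_samples",
]


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, HeightMap) else np.asarray(x, dtype=float)


def mse(a, b) -> float:
    """Mean squared error between two height maps (squared micrometers)."""
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise DimensionError(f"shape mismatch: {av.shape} vs {bv.shape}")
    return float(np.mean((av - bv) ** 2))


def ssim(a, b, data_range: float, window: int = 7) -> float:
    """Structural similarity index between two height maps.

    ``data_range`` is the dynamic range L of the data (for bead profiles,
    the maximum of the ideal model); ``window`` is the side of the uniform
    local window and must be odd and no larger than the image.
    """
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise DimensionError(f"shape mismatch: {av.shape} vs {bv.shape}")
    if data_range <= 0:
        raise ParameterError("data_range must be positive")
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be an odd integer >= 3, got {window}")
    if window > min(av.shape):
        raise ParameterError(
            f"window {window} exceeds image extent {min(av.shape)}"
        )
    C1 = (0.01 * data_range) ** 2
    C2 = (0.03 * data_range) ** 2
    np_win = window * window
    cov_norm = np_win / (np_win - 1)  # sample covariance

    def f(im):
        return ndimage.uniform_filter(im, size=window, mode="reflect")

    ux, uy = f(av), f(bv)
    uxx, uyy, uxy = f(av * av), f(bv * bv), f(av * bv)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    s = ((2 * ux * uy + C1) * (2 * vxy + C2)) / (
        (ux * ux + uy * uy + C1) * (vx + vy + C2)
    )
    pad = (window - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def background_rms(h, object_mask: np.ndarray) -> float:
    """Root-mean-square height over non-object pixels (micrometers)."""
    hv = _values(h)
    object_mask = np.asarray(object_mask, dtype=bool)
    if object_mask.shape != hv.shape:
        raise DimensionError("object mask shape differs from height map")
    bg = ~object_mask
    if not np.any(bg):
        raise LevelingError("object mask leaves no background pixels")
    return float(np.sqrt(np.mean(hv[bg] ** 2)))


@dataclass(frozen=True)
class MetricReport:
    """Per-sample metric rows plus per-method averages."""

    rows: pd.DataFrame

    def averages(self) -> pd.DataFrame:
        return (
            self.rows.groupby("method", sort=False)[["ssim", "mse", "background_rms"]]
            .mean()
            .reset_index()
        )

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


_RECONSTRUCTORS = {
    Method.CONVENTIONAL: "conventional",
    Method.RACOHS: "racohs",
    Method.GAUSSIAN: "gaussian_baseline",
}


def _run_method(method: Method, ref, obj, optics, NR, seed, SW, sigma):
    if method == Method.CONVENTIONAL:
        return reconstruct_conventional(ref, obj, optics, SW=SW)
    if method == Method.RACOHS:
        return reconstruct_racohs(ref, obj, optics, NR=NR, seed=seed, SW=SW)
    if method == Method.GAUSSIAN:
        conv = reconstruct_conventional(ref, obj, optics, SW=SW)
        return gaussian_baseline(conv, sigma=sigma)
    raise ParameterError(f"unknown method {method}")


def compare_methods(
    samples: Sequence[tuple[Hologram, Hologram, Phantom]],
    methods: Sequence[Method | str],
    optics: OpticalParameters,
    NR: int = 20,
    seed: int = 0,
    SW: Optional[int] = None,
    sigma: float = 2.0,
    window: int = 7,
) -> MetricReport:
    """Score every method on every (ref, obj, truth) sample.

    SSIM uses the ideal model's maximum as the data range; MSE is in
    squared micrometers on leveled maps; background RMS uses the phantom
    support (plus nothing else) as the object mask.
    """
    if len(samples) == 0:
        raise ParameterError("at least one sample is required")
    methods = [Method(m) for m in methods]
    rows = []
    for k, (ref, obj, phantom) in enumerate(samples):
        truth = phantom.height.values
        data_range = float(truth.max()) if truth.max() > 0 else 1.0
        obj_mask = truth > 0
        for method in methods:
            res = _run_method(method, ref, obj, optics, NR, seed, SW, sigma)
            hv = res.height.values
            rows.append(
                {
                    "sample_id": k,
                    "method": method.value,
                    "ssim": ssim(hv, truth, data_range=data_range, window=window),
                    "mse": mse(hv, truth),
                    "background_rms": background_rms(hv, obj_mask),
                }
            )
    return MetricReport(rows=pd.DataFrame(rows))


def bench_sphere_samples(
    n_samples: int = 10,
    diameter: float = 10.04,
    grid: tuple[int, int] = (256, 256),
    pitch: float = 0.11,
    noise_sigma: float = 0.02,
    envelope_sigma: Optional[float] = None,
    seed: int = 0,
    optics: Optional[OpticalParameters] = None,
) -> list[tuple[Hologram, Hologram, Phantom]]:
    """Seeded noisy microsphere hologram pairs for the comparison bench.

    Samples differ by their camera-noise realization (seeds derived from
    ``seed``); the bead, carrier and envelope are held fixed. Envelope
    defaults to one third of the grid side (illumination falling to ~10%
    in the corners), spreading the DC term broadly as in a real beam.
    """
    if optics is None:
        optics = OpticalParameters(
            n_object=1.5983, n_medium=1.49, pixel_pitch=pitch
        )
    if envelope_sigma is None:
        envelope_sigma = min(grid) / 3.0
    phantom = sphere_chord_phantom(diameter, grid, pitch)
    samples = []
    for k in range(n_samples):
        cfg = SimulationConfig(
            optics=optics,
            beam_envelope_sigma=envelope_sigma,
            noise_sigma=noise_sigma,
            grid=grid,
            seed=(seed * 1009 + k) % (2**31),
        )
        ref, obj = simulate_hologram_pair(phantom, cfg)
        samples.append((ref, obj, phantom))
    return samples
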