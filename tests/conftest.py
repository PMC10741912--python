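"""Shared fixtures: optical presets and small simulated hologram pairs."""

import numpy as np
import pytest

from racohs import (
    OpticalParameters,
    SimulationConfig,
    simulate_hologram_pair,
    sphere_chord_phantom,
)

RBC_OPTICS = OpticalParameters(
    wavelength=0.532, n_object=1.42, n_medium=1.34, pixel_pitch=0.055
)
BEAD_OPTICS = OpticalParameters(
    wavelength=0.532, n_object=1.5983, n_medium=1.49, pixel_pitch=0.055
)


@pytest.fixture(scope="session")
def bead_optics():
    return BEAD_OPTICS


@pytest.fixture(scope="session")
def rbc_optics():
    return RBC_OPTICS


@pytest.fixture(scope="session")
def noiseless_sphere_pair():
    """Noiseless 256x256 bead hologram pair with its phantom (fast t1 twin)."""
    phantom = sphere_chord_phantom(10.04, (256, 256), pitch=0.055)
    cfg = SimulationConfig(
        optics=BEAD_OPTICS, noise_sigma=0.0, beam_envelope_sigma=None,
        grid=(256, 256), seed=0,
    )
    ref, obj = simulate_hologram_pair(phantom, cfg)
    return ref, obj, phantom


@pytest.fixture(scope="session")
def noisy_sphere_pair():
    """One noisy 256x256 bead pair with beam envelope (bench conditions).

    Sampled at 0.11 um pitch: the bead's edge spectrum then far exceeds the
    window band, putting the single-window reconstruction in the noisy,
    unwrap-error-prone regime that ensemble averaging is designed to fix.
    """
    phantom = sphere_chord_phantom(10.04, (256, 256), pitch=0.11)
    cfg = SimulationConfig(
        optics=OpticalParameters(
            wavelength=0.532, n_object=1.5983, n_medium=1.49, pixel_pitch=0.11
        ),
        noise_sigma=0.02, beam_envelope_sigma=256 / 3.0,
        grid=(256, 256), seed=42,
    )
    ref, obj = simulate_hologram_pair(phantom, cfg)
    return ref, obj, phantom


@pytest.fixture(scope="session")
def noiseless_rbc_pair():
    """Noiseless 256x256 discocyte pair: a gentle-phase object whose band
    fits every shifted window, so all ensemble terms are interchangeable."""
    from racohs import rbc_biconcave_phantom

    phantom = rbc_biconcave_phantom(7.8, 2.4, (256, 256), pitch=0.055)
    cfg = SimulationConfig(
        optics=RBC_OPTICS, noise_sigma=0.0, beam_envelope_sigma=None,
        grid=(256, 256), seed=0,
    )
    ref, obj = simulate_hologram_pair(phantom, cfg)
    return ref, obj, phantom


def spanning_tree_unwrap(wrapped: np.ndarray) -> np.ndarray:
    """Independent unwrap oracle: integrate wrapped gradients along a fixed
    spanning tree (down the first column, then across each row).

    Valid for residue-free fields, where every integration path agrees.
    """
    from racohs import wrap_phase

    out = np.zeros_like(wrapped)
    out[0, 0] = wrapped[0, 0]
    col_steps = wrap_phase(np.diff(wrapped[:, 0]))
    out[1:, 0] = out[0, 0] + np.cumsum(col_steps)
    row_steps = wrap_phase(np.diff(wrapped, axis=1))
    out[:, 1:] = out[:, :1] + np.cumsum(row_steps, axis=1)
    return out


def smooth_random_field(rng: np.random.Generator, shape=(64, 64), n_modes=6):
    """Random band-limited surface with per-pixel gradients safely below pi."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    field = np.zeros(shape)
    for _ in range(n_modes):
        fy, fx = rng.uniform(-0.04, 0.04, size=2)
        amp = rng.uniform(0.5, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        field += amp * np.sin(2 * np.pi * (fx * xx + fy * yy) + phase)
    return field
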