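"""Run configuration: validated defaults, JSON round-trip, nm/um boundary.

Internally every length is micrometers. Config files may give the
wavelength in nanometers under ``wavelength_nm``; it is converted once at
the boundary. Defaults describe the reference setup: 532 nm source, red
blood cells (n = 1.42) in blood plasma (n = 1.34), 2.2 um sensor pitch
behind a 40x objective (0.055 um at the object plane), NR = 20 random
window centers, window side 2/3 of the maximum square, Gaussian-baseline
sigma 2 px.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .exceptions import ValidationError
from .phase import OpticalParameters

__all__ = ["RunConfig", "load_config", "save_config", "POLYSTYRENE_IN_MEDIUM"]

# refractive indices at 532 nm for the polystyrene bead control sample
POLYSTYRENE_IN_MEDIUM = {"n_object": 1.5983, "n_medium": 1.49}

_KNOWN_KEYS = {
    "wavelength_um",
    "wavelength_nm",
    "n_object",
    "n_medium",
    "pixel_pitch_um",
    "nr",
    "sw_fraction",
    "sigma",
    "seed",
    "verbosity",
}


@dataclass(frozen=True)
class RunConfig:
    optics: OpticalParameters = field(default_factory=OpticalParameters)
    nr: int = 20
    sw_fraction: float = 2.0 / 3.0
    sigma: float = 2.0
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.nr < 1:
            raise ValidationError(f"nr: must be >= 1, got {self.nr}")
        if not (0.5 < self.sw_fraction < 1.0):
            raise ValidationError(
                f"sw_fraction: must lie strictly between 0.5 and 1, got {self.sw_fraction}"
            )
        if self.sigma <= 0:
            raise ValidationError(f"sigma: must be positive, got {self.sigma}")

    def to_dict(self) -> dict:
        return {
            "wavelength_um": self.optics.wavelength,
            "n_object": self.optics.n_object,
            "n_medium": self.optics.n_medium,
            "pixel_pitch_um": self.optics.pixel_pitch,
            "nr": self.nr,
            "sw_fraction": self.sw_fraction,
            "sigma": self.sigma,
            "seed": self.seed,
            "verbosity": self.verbosity,
        }


def _config_from_dict(d: dict) -> RunConfig:
    unknown = set(d) - _KNOWN_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "wavelength_nm" in d and "wavelength_um" in d:
        raise ValidationError("give wavelength_nm or wavelength_um, not both")
    wavelength = d.get("wavelength_um", 0.532)
    if "wavelength_nm" in d:
        wavelength = float(d["wavelength_nm"]) / 1000.0
    try:
        optics = OpticalParameters(
            wavelength=float(wavelength),
            n_object=float(d.get("n_object", 1.42)),
            n_medium=float(d.get("n_medium", 1.34)),
            pixel_pitch=float(d.get("pixel_pitch_um", 0.055)),
        )
    except Exception as exc:
        raise ValidationError(f"optics: {exc}") from exc
    return RunConfig(
        optics=optics,
        nr=int(d.get("nr", 20)),
        sw_fraction=float(d.get("sw_fraction", 2.0 / 3.0)),
        sigma=float(d.get("sigma", 2.0)),
        seed=int(d.get("seed", 0)),
        verbosity=int(d.get("verbosity", 0)),
    )


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration; unknown keys rejected."""
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(d, dict):
        raise ValidationError(f"{path}: config must be a JSON object")
    return _config_from_dict(d)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2)
        fh.write("\n")
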