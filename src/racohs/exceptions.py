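"""Exception hierarchy for the reconstruction pipeline.

Every error raised by this package derives from :class:`RacohsError`, so
callers (and the CLI) can catch one type. Subclasses mark which stage of
the pipeline rejected its input.
"""


class RacohsError(Exception):
    """Base class for all errors raised by this package."""


class DimensionError(RacohsError, ValueError):
    """An input grid has the wrong rank, size, or mismatched shape."""


class NoSidebandError(RacohsError, ValueError):
    """No nonzero spectral bin exists outside the DC exclusion region."""


class GeometryError(RacohsError, ValueError):
    """The sideband peak position admits no valid windowing geometry."""


class WindowSizeError(RacohsError, ValueError):
    """A window side length violates the Rm/2 < SW < Rm constraint."""


class SamplingError(RacohsError, ValueError):
    """More window centers requested than the eligible square contains."""


class BoundsError(RacohsError, ValueError):
    """A window overruns the spectral grid."""


class UnwrapError(RacohsError, RuntimeError):
    """Phase unwrapping could not produce a usable surface."""


class ParameterError(RacohsError, ValueError):
    """Invalid optical or method parameter (e.g. zero refractive contrast)."""


class LevelingError(RacohsError, ValueError):
    """Background leveling was asked to fit an empty background."""


class FormatError(RacohsError, ValueError):
    """An image file is not a single-channel 8/16-bit raster."""


class ValidationError(RacohsError, ValueError):
    """A configuration record failed validation."""
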