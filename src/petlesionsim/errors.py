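"""Exception hierarchy.

Every error raised by the package derives from :class:`PetLesionSimError`
so callers can catch the whole family; the leaf classes mirror the kinds of
contract violation the individual stages can produce.
"""


class PetLesionSimError(Exception):
    """Base class for all package errors."""


class ConfigError(PetLesionSimError, ValueError):
    """Invalid or inconsistent configuration values."""


class SizingError(ConfigError):
    """A requested geometry does not fit on the requested grid."""


class GeometryError(PetLesionSimError, ValueError):
    """Incompatible grids / sinogram geometries or disjoint world extents."""


class ValidationError(PetLesionSimError, ValueError):
    """Array contents violate a physical contract (negative activity, ...)."""


class RegionLookupError(PetLesionSimError, KeyError):
    """A label or tissue class has no entry where one is required."""


class EmptyROIError(PetLesionSimError, ValueError):
    """A region of interest rasterized to zero voxels."""


class DomainError(PetLesionSimError, ValueError):
    """A scalar argument is outside the mathematical domain of an operation."""


class InsufficientDataError(PetLesionSimError, ValueError):
    """Too few observations for the requested statistical test."""


class VolumeIOError(PetLesionSimError, OSError):
    """Reading or writing an image volume failed; message names the path."""
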