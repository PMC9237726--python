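"""Exception hierarchy.

Every error raised by specmap derives from :class:`SpecmapError`, so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class SpecmapError(Exception):
    """Base class for all specmap errors."""


class FormatError(SpecmapError):
    """A delimited-text file could not be parsed (bad token, ragged row...)."""


class IncompatibleAxesError(SpecmapError):
    """Wavenumber axes differ where identical axes are required."""


class AnnotationError(SpecmapError):
    """Annotation table is missing a sample or a requested variable."""


class WindowError(SpecmapError):
    """A wavenumber window does not overlap the axis as required."""


class SpacingError(SpecmapError):
    """Axis spacing violates the uniformity a transform requires."""


class ParameterError(SpecmapError):
    """An operation parameter is out of its valid range."""


class MaskError(SpecmapError):
    """A QC mask is inconsistent with the data it is applied to."""


class DataError(SpecmapError):
    """The data itself cannot support the requested operation."""


class DegenerateSpectrumError(SpecmapError):
    """A spectrum with zero norm reached an operation that cannot handle it."""


class ConfigurationError(SpecmapError):
    """A configuration (coefficients, scene spec, run config) is invalid."""


class LabelError(SpecmapError):
    """Cluster labels are not aligned with the map they describe."""


class ShapeError(SpecmapError):
    """A vector/grid shape mismatch (e.g. length != nx * ny)."""
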