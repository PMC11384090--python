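"""Exception types shared across the package."""


class VertemapError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(VertemapError):
    """Input file violates the expected volume format (dimensionality, dtype)."""


class OrientationError(VertemapError):
    """Orientation metadata is missing or degenerate."""


class LabelError(VertemapError):
    """A requested vertebra label is absent or malformed."""


class EmptyMaskError(VertemapError):
    """An operation that needs masked voxels received an empty mask."""


class EmptyRunError(VertemapError):
    """A 1D resampling run contained no masked samples."""


class GeometryError(VertemapError):
    """Geometric precondition violated (overlap, degenerate extent, range)."""
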