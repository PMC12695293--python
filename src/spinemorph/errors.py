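"""Exception hierarchy for spinemorph.

All package errors derive from :class:`SpinemorphError` so callers (and the
batch CLI, which must isolate per-file failures) can catch one base class.
"""


class SpinemorphError(Exception):
    """Base class for all spinemorph errors."""


class MaskFormatError(SpinemorphError):
    """Input file is not a readable single-channel label image."""


class MaskValidationError(SpinemorphError):
    """Pixel values are inconsistent with the label scheme."""

    def __init__(self, message: str, offending_codes=()):
        super().__init__(message)
        self.offending_codes = tuple(offending_codes)


class MissingStructureError(SpinemorphError):
    """A named structure required for a measurement is absent from the mask."""

    def __init__(self, structure: str, message: str | None = None):
        super().__init__(message or f"structure {structure!r} is absent from the mask")
        self.structure = structure


class DegenerateGeometryError(SpinemorphError):
    """Geometry does not admit the requested measurement (coincident
    centroids, zero summed vertebral-body height, no eligible chords)."""


class DimensionError(SpinemorphError):
    """Two masks that must be compared pixel-wise have different shapes."""


class InsufficientDataError(SpinemorphError):
    """Too few paired observations for the requested statistic."""


class UndefinedCorrelationError(SpinemorphError):
    """Correlation undefined because one series is constant."""


class PhantomGeometryError(SpinemorphError):
    """A phantom structure does not fit inside the requested grid."""

    def __init__(self, structure: str, message: str | None = None):
        super().__init__(message or f"structure {structure!r} exceeds the phantom grid")
        self.structure = structure
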