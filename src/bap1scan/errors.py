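"""Exception hierarchy for the pipeline.

Every error raised by this package derives from :class:`Bap1ScanError`, so
callers can catch pipeline failures without masking programming errors.
"""


class Bap1ScanError(Exception):
    """Base class for all package errors."""


class FormatError(Bap1ScanError):
    """A file does not conform to the expected dialect (missing column,
    missing feature, malformed row)."""


class GeometryError(Bap1ScanError):
    """Invalid or inconsistent geometry (self-intersecting ROI, missing
    base polyline where one is required)."""


class ValidationError(Bap1ScanError):
    """An input value violates a documented precondition or invariant."""


class CalibrationError(Bap1ScanError):
    """Exemplar calibration is degenerate: the designated positive cell is
    not brighter than the designated negative cell.  In practice this is
    the signal to re-pick exemplars (e.g. pigment mistaken for chromogen)."""


class EmptyCompartmentError(Bap1ScanError):
    """A compartment contains no classifiable (positive or negative) cells."""


class NoValidSpotError(Bap1ScanError):
    """No candidate scan window satisfies the minimum-cellularity constraint."""
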