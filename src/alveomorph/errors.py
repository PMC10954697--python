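"""Exception hierarchy for alveomorph.

All package errors derive from :class:`AlveomorphError` so callers can catch
one base type at pipeline boundaries.
"""


class AlveomorphError(Exception):
    """Base class for all alveomorph errors."""


class InvalidPolygonError(AlveomorphError):
    """Polygon trace fails a geometric precondition.

    Raised for traces with fewer than 3 vertices, self-intersections, or
    (numerically) zero signed area. Malformed traces are rejected, never
    repaired.
    """


class ContainmentError(AlveomorphError):
    """Inner border is not strictly contained in the outer border."""


class SegmentationFailureError(AlveomorphError):
    """No closed wall band could be extracted from an image."""


class SegmentationAmbiguityError(AlveomorphError):
    """Multiple candidate wall bands found where exactly one was expected."""

    def __init__(self, message: str, n_regions: int):
        super().__init__(message)
        self.n_regions = n_regions


class InsufficientDataError(AlveomorphError):
    """Too few observations for the requested statistical operation."""


class DegenerateFitError(AlveomorphError):
    """Regression predictor has zero variance."""


class FieldOfViewError(AlveomorphError):
    """A trace does not fit inside the rendering field of view."""


class TraceParseError(AlveomorphError):
    """A trace table row or pairing is malformed."""
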