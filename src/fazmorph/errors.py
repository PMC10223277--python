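"""Exception and warning hierarchy for the FAZ morphometry pipeline."""


class FazMorphError(Exception):
    """Base class for all fazmorph errors."""


class NoOverlayFound(FazMorphError):
    """No pixel in the image matched the overlay colour specification."""


class AmbiguousOverlayWarning(UserWarning):
    """Matched overlay pixels form more than one connected component.

    Warning-level: the point set is still returned; the component count is
    reported in the message.
    """


class ParseError(FazMorphError):
    """A contour file could not be parsed (malformed rows or schema)."""


class MetadataError(FazMorphError):
    """Contour metadata is missing or holds an invalid enum value."""


class DegenerateContour(FazMorphError):
    """Fewer than 3 distinct points, or all points collinear."""


class ZeroRadius(FazMorphError):
    """All contour points coincide with the centre; acircularity undefined."""


class ShapeOutOfBounds(FazMorphError):
    """A synthetic shape does not fit inside the requested image."""


class InvalidSpec(FazMorphError):
    """A synthetic cohort specification violates its invariants."""


class MissingCriterion(FazMorphError):
    """A summary cell lacks one of the two delimitation criteria."""


class EmptyInput(FazMorphError):
    """An aggregation step received no records."""
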