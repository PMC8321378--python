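"""Exception types shared across the package."""


class SpagenError(Exception):
    """Base class for all package-specific errors."""


class DegenerateMaskError(SpagenError, ValueError):
    """A segmentation mask has no disc pixels (or is otherwise unusable)."""


class GeometryError(SpagenError, ValueError):
    """A geometric precondition is violated (e.g. ray center outside region)."""


class UndefinedMetricError(SpagenError, ZeroDivisionError):
    """A metric's denominator is zero for the given confusion counts."""


class FittingError(SpagenError, ValueError):
    """Model fitting cannot proceed (e.g. a diagnostic group is absent)."""
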