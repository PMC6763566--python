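"""Exception hierarchy for the HCSA pipeline.

Every stage raises a subclass of :class:`HcsaError`, so callers (and the
command-line driver) can distinguish pipeline failures from programming
errors and report the offending stage.
"""


class HcsaError(Exception):
    """Base class for all pipeline errors."""


class ShapeMismatchError(HcsaError):
    """Frames (or a frame and a mask) do not share one shape."""


class InsufficientFramesError(HcsaError):
    """An image series needs at least two frames."""


class DegeneratePolygonError(HcsaError):
    """Polygon has fewer than three vertices."""


class InvalidPolygonError(HcsaError):
    """Polygon is self-intersecting or otherwise not simple."""


class BoundsError(HcsaError):
    """A vertex lies outside the image it was drawn on."""


class ConfigError(HcsaError):
    """Invalid or inconsistent run configuration."""


class DegenerateContrastError(HcsaError):
    """Contrast computation hit a series with zero dynamic range."""


class DegenerateInputError(HcsaError):
    """Thresholding needs at least two distinct values."""


class NoPulsatilityError(HcsaError):
    """The blush trace is constant; no cardiac phases can be selected."""


class MissingRoiError(HcsaError):
    """A selected cardiac-phase frame has no ventricle outline."""


class UndefinedMetricError(HcsaError):
    """A denominator (EDBA or tEDA) is zero, so the metric is undefined."""


class EmptyResultsError(HcsaError):
    """A results table was requested for zero embryos."""


class ParameterError(HcsaError):
    """Phantom parameters violate their invariants."""
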