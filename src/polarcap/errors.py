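"""Exception hierarchy for polarcap.

Every stage raises a subclass of :class:`PolarcapError` so pipeline drivers
can attach cell/frame context while propagating.
"""


class PolarcapError(Exception):
    """Base class for all polarcap errors."""


class InvalidConfigError(PolarcapError, ValueError):
    """A scene or run configuration violates its invariants."""


class NoCellError(PolarcapError, ValueError):
    """A cell mask is empty."""


class AmbiguousMaskError(PolarcapError, ValueError):
    """A cell mask contains more than one connected component."""


class InconsistentInputError(PolarcapError, ValueError):
    """Inputs that must agree (lengths, channels, grids) do not."""


class DegenerateProfileError(PolarcapError, ValueError):
    """A profile is constant and has no usable peak/extremum."""


class ResolutionError(PolarcapError, ValueError):
    """A resampling grid is too coarse for the profile."""


class EmptySelectionError(PolarcapError, ValueError):
    """A frame/cell selection matched nothing."""


class UndefinedMetricError(PolarcapError, ValueError):
    """A metric is undefined for the given inputs (e.g. empty truth mask)."""


class InvalidQuantileError(PolarcapError, ValueError):
    """Quantile outside (0, 1]."""


class InvalidInputError(PolarcapError, ValueError):
    """Generic invalid numerical input to a statistics routine."""


class UndefinedOrientationError(PolarcapError, ValueError):
    """Orientation requested for a zero-length displacement vector."""
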