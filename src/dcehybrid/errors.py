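"""Exception hierarchy for dcehybrid.

All errors raised by the library derive from :class:`DceHybridError` so
callers can catch everything with a single except clause; subclasses keep
the failure mode distinguishable (bad parameters vs. degenerate data vs.
failed fits).
"""


class DceHybridError(Exception):
    """Base class for all dcehybrid errors."""


class InvalidParameterError(DceHybridError, ValueError):
    """A physical parameter is outside its admissible range."""


class InvalidInputError(DceHybridError, ValueError):
    """Input data violate a structural precondition (length, grid, units)."""


class AlignmentError(InvalidInputError):
    """Two curves that must share a time grid do not."""


class FitFailureError(DceHybridError, RuntimeError):
    """A least-squares or root-finding procedure failed to converge."""


class InsufficientDataError(DceHybridError, ValueError):
    """Not enough valid samples to perform the requested estimation."""

class EmptySeriesError(InsufficientDataError):
    """Every sample of a series was masked invalid."""


class OutOfRangeError(DceHybridError, ValueError):
    """A signal target lies outside the attainable range of the model."""


class NoBolusError(DceHybridError, ValueError):
    """No contrast bolus could be detected in a plasma curve."""


class EmptyRegionError(DceHybridError, ValueError):
    """A requested ROI/label contains no voxels."""


class UndefinedStatisticError(DceHybridError, ValueError):
    """A summary statistic is undefined for the given values (e.g. CoV at mean ~ 0)."""
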