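"""Exception hierarchy.

Every error raised by olivephen derives from :class:`OlivePhenError`, so
callers can catch the whole family with one clause.  Subclasses mirror the
kind of contract that was broken (file format, physical validity, temporal
coverage, grid geometry, ...).
"""


class OlivePhenError(Exception):
    """Base class for all olivephen errors."""


class FormatError(OlivePhenError, ValueError):
    """A file or table does not have the expected columns/layout."""


class ValidationError(OlivePhenError, ValueError):
    """A record violates a physical invariant (e.g. tmin > tmax)."""


class ContiguityError(OlivePhenError, ValueError):
    """A daily series has a gap or duplicated dates."""


class WindowError(OlivePhenError, ValueError):
    """A requested time window is not covered by the available data."""


class GridError(OlivePhenError, ValueError):
    """A lat/lon grid is malformed (irregular step, missing axis...)."""


class BoundsError(OlivePhenError, ValueError):
    """A point lies outside the grid bounds, or a parameter interval is empty."""


class DataError(OlivePhenError, ValueError):
    """Observation/season bookkeeping problem (missing season, too few obs)."""


class OptimizerError(OlivePhenError, RuntimeError):
    """The optimizer met a non-finite objective value."""


class StatisticsError(OlivePhenError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class AlignmentError(OlivePhenError, ValueError):
    """Two rasters do not share the same grid/phase and cannot be combined."""
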