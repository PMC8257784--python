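"""Exception hierarchy.

All errors raised on bad inputs derive from :class:`AxonFidError`, which
itself derives from ``ValueError`` so that callers who do not care about
the fine-grained class can catch the standard type.
"""


class AxonFidError(ValueError):
    """Base class for all package-specific errors."""


class InvalidParameterError(AxonFidError):
    """A configuration or function parameter is outside its valid range."""


class InvalidInputError(AxonFidError):
    """Input data violate a structural precondition (shape, count, geometry)."""


class InsufficientDataError(AxonFidError):
    """Not enough data to compute the requested quantity."""


class DegenerateDataError(AxonFidError):
    """Data are degenerate for the requested statistic (e.g. zero variance)."""


class ConfigError(AxonFidError):
    """A configuration file failed schema validation."""
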