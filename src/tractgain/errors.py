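"""Exception hierarchy shared across the pipeline stages."""


class TractgainError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TractgainError, ValueError):
    """Invalid parameter or configuration (CLI exit code 2)."""


class DataError(TractgainError, ValueError):
    """Invalid or degenerate data (CLI exit code 3)."""


class InsufficientDataError(DataError):
    """Record too short for the requested spectral estimate."""


class EmptyPathwayError(DataError):
    """No channels or streamlines available for a requested pathway."""
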