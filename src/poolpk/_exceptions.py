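"""Exception hierarchy shared across the package."""


class PoolPKError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PoolPKError, ValueError):
    """A file does not conform to the expected tabular schema."""


class ValidationError(PoolPKError, ValueError):
    """Input values violate a domain precondition (negative time, free > total, ...)."""


class InsufficientDataError(PoolPKError, ValueError):
    """Too few usable points for the requested computation."""


class NoTerminalPhaseError(PoolPKError, ValueError):
    """No declining log-linear terminal phase could be identified."""
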