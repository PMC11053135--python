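"""Exception hierarchy shared across the package."""


class EESMapError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EESMapError, ValueError):
    """An argument violates a documented precondition."""


class ProtocolError(EESMapError, ValueError):
    """A stimulation protocol is internally inconsistent (e.g. overlapping blocks)."""


class EmptySelectionError(EESMapError, ValueError):
    """A selection (events, measurements, animals) matched nothing."""


class TruncationError(EESMapError, ValueError):
    """An epoch or interval extends past the end of the recorded trace."""


class DegenerateTestError(EESMapError, ValueError):
    """A statistical test has no information to work with (e.g. all-zero differences)."""


class DegenerateBackgroundError(EESMapError, ValueError):
    """Background metric is zero, so a percent-of-background is undefined."""


class InvalidIntervalError(EESMapError, ValueError):
    """A time interval is empty, reversed, overlapping or out of range."""


class FormatError(EESMapError, ValueError):
    """A session container file is missing or ill-formed; the message names the file."""


class ValidationError(EESMapError, ValueError):
    """Loaded data violates a container invariant (event times, array lengths...)."""
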