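"""Exception hierarchy shared by all heatcraft modules.

Every error the library raises deliberately derives from :class:`HeatcraftError`
so that callers (notably the CLI driver) can distinguish pipeline failures
from programming bugs.
"""


class HeatcraftError(Exception):
    """Base class for all heatcraft errors."""


class FormatError(HeatcraftError):
    """Unreadable or unrecognized input file format."""


class ValidationError(HeatcraftError):
    """Input violates a stated precondition (shape, range, selection bounds)."""


class DomainError(HeatcraftError):
    """A value lies outside the mathematical domain of the requested operation
    (e.g. a non-positive cell under log normalization, a constant vector under
    a correlation distance)."""
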