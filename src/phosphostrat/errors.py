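"""Exception hierarchy shared across the package."""


class PhosphostratError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PhosphostratError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(PhosphostratError, ValueError):
    """Malformed input table; the message points at the offending row/column."""


class ValidationError(PhosphostratError, ValueError):
    """Inputs violate an operation's contract (overlapping groups, unknown ids, ...)."""


class DegenerateInputError(PhosphostratError, ValueError):
    """Statistically degenerate input (zero variance, empty reference set, ...)."""
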