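"""Exception hierarchy.

``InputError`` marks bad data (shape/content), ``ConfigurationError`` bad
parameters or missing configuration, ``NumericError`` solver failures.
All derive from builtins so callers may catch ``ValueError``/``RuntimeError``.
"""


class RankpruneError(Exception):
    """Base class for all package errors."""


class InputError(RankpruneError, ValueError):
    """The supplied data violates a precondition."""


class ConfigurationError(RankpruneError, ValueError):
    """A parameter or configuration value is invalid or missing."""


class NumericError(RankpruneError, RuntimeError):
    """A numerical routine failed to converge or produced invalid output."""
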