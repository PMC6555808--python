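"""Error hierarchy.

Validation errors signal bad data (table contents, label values, shape
mismatches); configuration errors signal bad requests (unknown algorithm,
unknown dialect, invalid override keys). The CLI maps them onto distinct
exit codes.
"""


class SleepWakeError(Exception):
    """Base class for all package errors."""


class ValidationError(SleepWakeError, ValueError):
    """Input data violates a documented precondition or invariant."""


class ConfigurationError(SleepWakeError, ValueError):
    """A name, key or option does not resolve against the registries."""
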