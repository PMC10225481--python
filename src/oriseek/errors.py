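"""Exception hierarchy shared across the package."""


class OriSeekError(Exception):
    """Base class for all package errors."""


class InputError(OriSeekError):
    """Malformed or unreadable input data."""


class ConfigError(OriSeekError):
    """Invalid configuration value (e.g. a bad IUPAC motif)."""


class ParameterError(OriSeekError):
    """Simulation or analysis parameters that cannot be satisfied."""


class UnsupportedOperationError(OriSeekError):
    """Operation not defined for this input (e.g. terminus on a draft)."""
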