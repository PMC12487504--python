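"""Exception types shared across the package."""


class MIHMMError(Exception):
    """Base class for all package errors."""


class ValidationError(MIHMMError):
    """A value violates a documented invariant or precondition."""


class FormatError(MIHMMError):
    """An input file does not conform to the expected dialect."""


class ConfigError(MIHMMError):
    """A run configuration is invalid; the message names the failing field."""
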