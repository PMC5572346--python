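"""Exception hierarchy."""


class RhizoscopeError(Exception):
    """Base class for all package errors."""


class FormatError(RhizoscopeError):
    """A file does not conform to the expected dialect (missing column, ...)."""


class ValidationError(RhizoscopeError):
    """Contents parsed but violate an invariant (negative count, bad EC, ...)."""


class ConfigError(RhizoscopeError):
    """A parameter or configuration value is out of its valid range."""
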