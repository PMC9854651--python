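"""Exception hierarchy shared across the package.

Validation and configuration problems map to CLI exit code 2; everything
else is exit code 1.
"""


class PigmentNetError(Exception):
    """Base class for all package errors."""


class FormatError(PigmentNetError):
    """An input file does not match its declared dialect or layout."""


class ValidationError(PigmentNetError):
    """Input content violates a contract (bad class string, p outside [0,1], ...)."""


class ConfigurationError(PigmentNetError):
    """A parameter value is outside its allowed range or an input set is empty."""
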