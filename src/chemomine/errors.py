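"""Exception hierarchy shared across the pipeline."""


class ChemomineError(Exception):
    """Base class for all package errors."""


class ValidationError(ChemomineError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(ValidationError):
    """A pattern string or file could not be parsed."""


class NoOrfError(ChemomineError):
    """A transcript contains no open reading frame of the required length."""


class ConfigurationError(ChemomineError):
    """A run configuration is incomplete or inconsistent."""
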