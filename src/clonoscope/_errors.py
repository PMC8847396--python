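"""Exception hierarchy shared across the package."""


class ClonoscopeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ClonoscopeError):
    """A file does not conform to the declared dialect (e.g. missing column)."""


class ValidationError(ClonoscopeError, ValueError):
    """An argument or record violates a stated precondition."""


class IntegrityError(ClonoscopeError):
    """Input data violates a uniqueness or consistency constraint."""
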