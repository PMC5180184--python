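"""Exception hierarchy shared by all aridflux modules."""


class AridfluxError(Exception):
    """Base class for all package errors."""


class ValidationError(AridfluxError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(AridfluxError, IOError):
    """A file exists but does not have the expected structure."""


class UnitsError(ValidationError):
    """Declared units do not match what an operation requires."""
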