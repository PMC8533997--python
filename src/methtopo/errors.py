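"""Exception types shared across the package."""


class MethtopoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MethtopoError, ValueError):
    """A file or table does not conform to the expected dialect."""


class ValidationError(MethtopoError, ValueError):
    """Inputs are well-formed but violate a semantic precondition."""
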