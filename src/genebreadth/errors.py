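"""Exception types shared across the package."""


class GeneBreadthError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GeneBreadthError, ValueError):
    """A file or table violates its format contract (duplicates, bad cells, ...)."""


class DomainError(GeneBreadthError, ValueError):
    """An argument violates a mathematical precondition (bounds, alignment, ...)."""
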