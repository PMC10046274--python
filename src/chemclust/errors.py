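"""Exception hierarchy shared across the package."""


class ChemclustError(Exception):
    """Base class for all package errors."""


class ValidationError(ChemclustError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(ChemclustError, ValueError):
    """A file does not conform to the expected on-disk format."""


class EnvironmentError_(ChemclustError, RuntimeError):
    """A required external component (e.g. the chemistry toolkit) is missing."""
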