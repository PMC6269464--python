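"""Exception hierarchy for the angioarch pipeline."""


class AngioArchError(Exception):
    """Base class for all package errors."""


class StackIOError(AngioArchError):
    """Raised when a stack cannot be read or written."""


class ConfigurationError(AngioArchError):
    """Raised when configuration values are inconsistent (e.g. mismatched
    voxel sizes, a normalization reference below a sample's own volume)."""


class DomainError(AngioArchError):
    """Raised when an operation's mathematical precondition fails
    (e.g. expanding an empty signal, fitting through identical abscissae)."""
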