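"""Shared exception hierarchy.

Exit-code mapping used by the CLI: ValidationError -> 1, ComputationError -> 2.
"""


class NanoSSbDError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(NanoSSbDError):
    """Invalid input data: schema violations, range errors, mass-balance breaks."""


class SchemaError(ValidationError):
    """A table or config does not match its declared schema (file/row/column named)."""


class ComputationError(NanoSSbDError):
    """A numerically well-formed input that cannot be computed on."""


class SingularSystemError(ComputationError):
    """The technology matrix is singular or ill-conditioned; names the
    unproducible product flow when one can be identified."""


class CannotCharacterizeError(ComputationError):
    """No characterization factor is resolvable at any data tier; the caller
    should fall back to a KPI-only assessment."""
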