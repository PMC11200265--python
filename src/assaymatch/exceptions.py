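"""Exception hierarchy shared across the package.

Every failure mode that callers are expected to handle gets its own class so
that batch drivers can report precisely which contract was violated (an
unparsable SMILES, a dimension mismatch, a degenerate label vector, ...)
instead of swallowing rows silently.
"""


class AssayMatchError(Exception):
    """Base class for all package errors."""


class InvalidMoleculeError(AssayMatchError):
    """A SMILES string could not be parsed into a molecular graph."""


class DimensionError(AssayMatchError):
    """Vector/matrix shapes do not line up."""


class InsufficientDataError(AssayMatchError):
    """Too few items for the requested statistic."""


class InvalidDocumentError(AssayMatchError):
    """An assay document violates its invariants (e.g. empty text)."""


class DuplicateKeyError(AssayMatchError):
    """Identifier that must be unique occurred more than once."""


class ConfigurationError(AssayMatchError):
    """A configuration value is out of its permitted range."""


class BatchTooSmallError(AssayMatchError):
    """Batch statistics need at least two rows."""


class DivergenceError(AssayMatchError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class DegenerateLabelError(AssayMatchError):
    """Labels contain a single class where two are required."""


class DegenerateCalibrationError(AssayMatchError):
    """Conformal calibration set is missing a class."""


class DegenerateScreenError(AssayMatchError):
    """A ranked screen has no actives (or no inactives) where required."""


class DegenerateInputError(AssayMatchError):
    """Statistical test input has zero variance or is otherwise degenerate."""


class ProtocolError(AssayMatchError):
    """Evaluation protocol violated (e.g. ragged replicate counts)."""


class GenerationError(AssayMatchError):
    """Synthetic-world generation could not satisfy its constraints."""


class ValidationError(AssayMatchError):
    """An input table violates the expected schema."""


class ArchiveError(AssayMatchError):
    """A model archive is missing, corrupt, or has an incompatible version."""
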