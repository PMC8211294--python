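"""Exception hierarchy used across the pipeline."""


class SoyieldError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SoyieldError):
    """Invalid configuration values (counts, ranges, fractions)."""


class PedigreeError(SoyieldError):
    """Malformed pedigree: cycles, duplicate or unresolvable identifiers."""


class MatrixError(SoyieldError):
    """Invalid relationship/correlation matrix (e.g. non-positive diagonal)."""


class GenerationError(SoyieldError):
    """Synthetic-data generation failed (e.g. a record without weather)."""


class FormatError(SoyieldError):
    """Input data does not match the expected schema/shape."""


class AssemblyError(SoyieldError):
    """Model inputs could not be assembled (missing weather or cluster)."""


class DivergenceError(SoyieldError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class EvaluationError(SoyieldError):
    """Evaluation requested on an empty or degenerate test set."""
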