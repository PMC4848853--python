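"""Exception hierarchy shared across the package."""


class StainStatError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StainStatError):
    """Incompatible spaces, bin counts or option combinations."""


class TrainingError(StainStatError):
    """Training cannot proceed (empty class, degenerate ROI, ...)."""


class ModelFormatError(StainStatError):
    """A model file is corrupt, inconsistent or of an unknown version."""


class ModelStateError(StainStatError):
    """An operation requires a finalized model."""


class DegenerateMatrixError(StainStatError):
    """A stain matrix is singular or its vectors are collinear."""


class EvaluationError(StainStatError):
    """Evaluation inputs are degenerate (one-class truth, zero variance...)."""


class SamplingError(StainStatError):
    """A phantom does not contain enough pixels of the requested class."""
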