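"""Exception hierarchy shared across the pipeline stages."""


class PharmriskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PharmriskError):
    """An invalid configuration object or synonym map."""


class PreconditionError(PharmriskError):
    """An operation was called on inputs that violate its contract."""


class LabelingError(PharmriskError):
    """A drug is missing from the label table."""


class LookupError_(PharmriskError):
    """Unknown drug or ADR term requested from a count table."""


class UndefinedPairError(PharmriskError):
    """PRR requested for a drug with an empty report margin (A+B = 0)."""


class RankingError(PharmriskError):
    """Feature ranking requires at least two classes."""


class SelectionError(PharmriskError):
    """Top-k selection with k larger than the number of features."""


class TrainingDivergenceError(PharmriskError):
    """GAN training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite GAN loss at epoch {epoch}")


class DegenerateClassError(PharmriskError):
    """A class has zero samples where a positive count is required."""


class NeighborError(PharmriskError):
    """A minority class is too small for k-nearest-neighbour SMOTE."""


class ShapeError(PharmriskError):
    """Mismatched row/column counts between pipeline artifacts."""


class SplitError(PharmriskError):
    """Stratified splitting impossible (a class has fewer than 2 samples)."""
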