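"""Exception hierarchy shared across the pipeline stages."""


class BaxlocError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(BaxlocError, ValueError):
    """A kinetic or configuration parameter violates its constraints."""


class ConfigurationError(BaxlocError, ValueError):
    """A cohort/run configuration is internally inconsistent."""


class InsufficientStandardsError(BaxlocError, ValueError):
    """Fewer than three titration points available for a standard curve."""


class NonMonotoneStandardError(BaxlocError, ValueError):
    """Fitted standard-curve slope is not positive."""


class NonpositiveAmountError(BaxlocError, ValueError):
    """Back-calculated protein amount is <= 0 and cannot enter a log-ratio."""


class MissingMarkerError(BaxlocError, KeyError):
    """A fractionation lane lacks its loading-control band (COX IV / beta-ACTIN)."""


class InvalidQuantificationError(BaxlocError, ValueError):
    """A localization input (relative mito/cyto amount) is nonpositive or non-finite."""


class PairingError(BaxlocError, ValueError):
    """Tumor and non-tumor records for a patient cannot be paired."""


class InsufficientCohortError(BaxlocError, ValueError):
    """Too few patients for the requested rank partition."""


class DegenerateInputError(BaxlocError, ValueError):
    """A statistic is undefined on the given data (zero variance etc.)."""


class DegenerateSampleError(BaxlocError, ValueError):
    """An expression sample has no observed values."""


class LabelingError(BaxlocError, ValueError):
    """Group labels do not define the required number of classes."""


class UndefinedDistanceError(BaxlocError, ValueError):
    """Too few pairwise-complete observations to define a distance."""


class InvalidRecordError(BaxlocError, ValueError):
    """A survival record violates its invariants (e.g. nonpositive time)."""


class UndefinedTestError(BaxlocError, ValueError):
    """The log-rank test is undefined (a stratum has no events)."""


class DegeneratePartitionError(BaxlocError, ValueError):
    """A clustering cut produced fewer than two nonempty clusters."""


class MissingSignatureError(BaxlocError, KeyError):
    """Requested signature genes are absent from the expression matrix."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"signature genes absent from matrix: {self.missing}")
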