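"""Exception hierarchy for the xmittn package."""


class XmittnError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(XmittnError):
    """A required column cannot be resolved in an input table."""


class ValidationError(XmittnError):
    """One or more records violate the data-model contracts.

    Carries per-row messages so a caller can report every offending
    record at once instead of failing on the first.
    """

    def __init__(self, message, row_errors=None):
        super().__init__(message)
        self.row_errors = list(row_errors or [])


class ConfigurationError(XmittnError):
    """Split-plan or pipeline configuration is infeasible."""


class DegenerateTrainingError(XmittnError):
    """Training labels contain a single class."""


class FeatureMismatchError(XmittnError):
    """A frozen model was handed a matrix with different features."""


class UndefinedGiniError(XmittnError):
    """Gini index requested for a single-class label vector."""


class InsufficientReferenceError(XmittnError):
    """Normal-reference group too small to define a z-score."""


class DegenerateReferenceError(XmittnError):
    """Normal-reference log-C3 values have zero spread."""


class InsufficientDataError(XmittnError):
    """Not enough longitudinal data in a stratum for the comparison."""


class RejectionBudgetError(XmittnError):
    """Rejection sampling could not satisfy a cohort constraint."""
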