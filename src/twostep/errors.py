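"""Exception hierarchy for the two-step workflow package."""


class TwoStepError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TwoStepError, ValueError):
    """A configuration object violates its invariants (names the offending field)."""


class DataError(TwoStepError, ValueError):
    """Input data are unusable for the requested computation."""


class SchemaError(DataError):
    """A cohort file does not conform to the documented column schema."""


class EstimationError(TwoStepError, RuntimeError):
    """Model estimation failed (non-convergence, quasi-complete separation)."""


class DerivationError(TwoStepError, RuntimeError):
    """A cutoff or threshold could not be derived from the supplied fit."""


class DegenerateThresholdError(DerivationError):
    """Lower threshold exceeded upper threshold; classes overlap too strongly
    for the requested sensitivity/specificity strategy."""
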