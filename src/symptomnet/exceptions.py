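"""Exception hierarchy for symptomnet."""


class SymptomNetError(Exception):
    """Base class for all symptomnet errors."""


class InvalidArgumentError(SymptomNetError, ValueError):
    """An argument violates a documented precondition."""


class CapacityError(SymptomNetError):
    """The requested enumeration is too large to run exhaustively."""


class FormatError(SymptomNetError):
    """Malformed tabular input (bad cell, missing column, wrong dialect)."""


class EmptyInputError(FormatError):
    """A data source contained no usable respondent rows."""


class DegenerateItemError(SymptomNetError):
    """An item is (numerically) constant, so correlations are undefined."""


class TooSmallSampleError(SymptomNetError):
    """Subsample below the estimation floor."""


class EstimationError(SymptomNetError):
    """Network estimation failed (singular matrix, no converged penalty)."""


class StabilityError(SymptomNetError):
    """Bootstrap procedure failed on too many resamples."""


class ConsistencyError(SymptomNetError):
    """Internal invariant broken, e.g. an included respondent whose
    dichotomized pattern is missing from the catalog (signals that the
    catalog was built under a different rule than the inclusion filter)."""


class SpecError(SymptomNetError):
    """Invalid synthetic-cohort specification (e.g. a planted partial
    correlation matrix that does not correspond to a positive definite
    precision matrix)."""
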