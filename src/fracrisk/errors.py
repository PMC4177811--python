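"""Exception hierarchy for fracrisk.

Every failure mode the public API promises to report loudly has its own
class, so callers can distinguish a malformed coefficient document from a
bad cohort row or a degenerate statistical input.
"""


class FracRiskError(Exception):
    """Base class for all fracrisk errors."""


class CoefficientSpecError(FracRiskError):
    """Coefficient document failed to parse (bad syntax, malformed number)."""


class IncompleteCoefficientsError(CoefficientSpecError):
    """A required (outcome, sex, variant, horizon) block is missing.

    The message names the missing block, e.g. ``"male hip weight"``.
    """


class ProfileError(FracRiskError):
    """A risk profile violates its domain invariants."""


class MissingPredictorError(ProfileError):
    """The predictor required by the chosen model variant is absent."""


class UnsupportedHorizonError(FracRiskError):
    """Requested horizon is not one the model defines (5 or 10 years)."""


class SchemaError(FracRiskError):
    """Cohort file does not match the declared column schema."""


class RecordValidationError(FracRiskError):
    """A cohort row violates record invariants; names the subject id."""

    def __init__(self, subject_id: str, message: str):
        self.subject_id = subject_id
        super().__init__(f"subject {subject_id!r}: {message}")


class EmptyCohortError(FracRiskError):
    """An operation requiring at least one record got an empty cohort."""


class DomainError(FracRiskError):
    """Numeric argument outside the operation's mathematical domain."""


class DegenerateOutcomeError(FracRiskError):
    """Outcome vector has no events or no non-events."""


class DegenerateGroupingError(FracRiskError):
    """Quantile grouping impossible (too few distinct predictions)."""


class PairingError(FracRiskError):
    """Paired vectors have mismatched lengths."""


class ThresholdError(FracRiskError):
    """Risk-category thresholds are not strictly increasing."""


class ConfigError(FracRiskError):
    """Synthetic-cohort configuration is invalid."""
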