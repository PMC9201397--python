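"""Exception hierarchy shared across the package."""


class BodyAgreeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BodyAgreeError):
    """A required column is missing or the table layout is unusable."""


class RowValidationError(BodyAgreeError):
    """A single row failed validation; carries the 0-based data-row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class EmptyCohortError(BodyAgreeError):
    """No usable rows remain after validation, or a write of zero records."""


class CohortError(BodyAgreeError):
    """Cohort-level invariant violation (e.g. duplicate subject ids)."""


class InsufficientDataError(BodyAgreeError):
    """A stratum or vector is too small for the requested statistic."""


class ParameterError(BodyAgreeError):
    """Synthetic-cohort parameters are invalid or infeasible."""


class DegenerateRegressionError(BodyAgreeError):
    """Regression input has zero variance on the predictor axis."""


class InsufficientGroupError(BodyAgreeError):
    """A comparison group has fewer than 2 members; names the group."""


class MissingCovariateError(BodyAgreeError):
    """A requested covariate is absent from (part of) the cohort."""


class ConfigError(BodyAgreeError):
    """Run configuration is incomplete or contradictory."""
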