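"""Exception hierarchy for the microclim package."""


class MicroclimError(Exception):
    """Base class for all package errors."""


class ValidationError(MicroclimError):
    """Input data violates a structural invariant (range, ordering, schema)."""


class ScheduleError(ValidationError):
    """A record falls outside the fixed six-per-day recording schedule."""


class DuplicateTimestampError(ValidationError):
    """Two records share a timestamp within one series."""


class IncompleteYearError(MicroclimError):
    """Strict-mode computation requires a full 12-month record."""


class DegenerateDataError(MicroclimError):
    """Statistical routine called on data with no usable variation."""


class DegenerateDesignError(MicroclimError):
    """Regression design matrix is rank-deficient (e.g. all elevations equal)."""


class ExtrapolationError(MicroclimError):
    """Prediction requested outside the fitted covariate range."""


class ConfigError(MicroclimError):
    """Run or generator configuration is invalid."""


class StageError(MicroclimError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
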