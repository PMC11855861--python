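"""Exception hierarchy; exit codes used by the CLI are attached here."""


class DemandtxError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ValidationError(DemandtxError, ValueError):
    """Bad inputs or configuration."""

    exit_code = 2


class UnfittableCurveError(ValidationError):
    """A consumption curve has too few positive points to fit."""


class NoUnitElasticPointError(ValidationError):
    """k too small for an interior expenditure maximum (k * ln10 <= e)."""


class ConvergenceError(DemandtxError, RuntimeError):
    """An optimizer failed from every start."""

    exit_code = 3

    def __init__(self, message, best_candidate=None):
        super().__init__(message)
        self.best_candidate = best_candidate


class StageError(DemandtxError, RuntimeError):
    """A pipeline stage failed; carries the stage name and original cause."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.exit_code = getattr(cause, "exit_code", 1)
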