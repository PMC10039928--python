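"""Typed exceptions raised across the package."""


class GxeError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(GxeError, ValueError):
    """A configuration value is outside its permitted range."""


class DomainError(GxeError, ValueError):
    """An input value is outside the mathematical domain of an operation."""


class DegenerateInputError(GxeError, ValueError):
    """Input is constant / empty in a way that makes the operation undefined."""


class RankDeficiencyError(GxeError, ValueError):
    """A regression design matrix is not full column rank."""


class SumstatsParseError(GxeError, ValueError):
    """A summary-statistics file is malformed."""


class UnidentifiableModelError(GxeError, ValueError):
    """A regression model cannot be identified from the given data."""


class ConvergenceError(GxeError, RuntimeError):
    """An iterative optimizer failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class PipelineStageError(GxeError, RuntimeError):
    """Wraps a stage failure with the stage name and exposure label."""

    def __init__(self, stage: str, exposure: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for exposure {exposure!r}: {cause}")
        self.stage = stage
        self.exposure = exposure
        self.cause = cause
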