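"""Exception hierarchy for immunoclock."""


class ImmunoclockError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ImmunoclockError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class ConfigMismatchError(ImmunoclockError, ValueError):
    """A config references a subset/protein/stimulus unknown to the panel."""


class EmptyPopulationError(ImmunoclockError, ValueError):
    """A cell population has no events where a value is required."""


class UndefinedFrequencyError(ImmunoclockError, ZeroDivisionError):
    """A frequency denominator (leukocyte or mononuclear events) is zero."""


class IncompleteSampleError(ImmunoclockError, ValueError):
    """A sample is missing one or more stimulation conditions."""


class EmptyMatrixError(ImmunoclockError, ValueError):
    """All features were removed by pre-processing."""


class ValidationError(ImmunoclockError, ValueError):
    """Generic argument validation failure."""


class DegenerateNetworkError(ImmunoclockError, ValueError):
    """Too few usable features to build a correlation network."""


class InsufficientDataError(ImmunoclockError, ValueError):
    """Too few complete cases for a regression."""


class PipelineStageError(ImmunoclockError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
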