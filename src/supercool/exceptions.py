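"""Exception hierarchy.

Separate classes let callers (and the CLI exit-code mapping) distinguish
bad input data, optimizer failures, and genuinely absent physical features.
"""


class SupercoolError(Exception):
    """Base class for all package errors."""


class DataValidationError(SupercoolError, ValueError):
    """Input table/record violates its schema or a physical invariant."""


class FitConvergenceError(SupercoolError, RuntimeError):
    """An optimizer failed, hit its bounds, or the fit is not trustworthy."""


class InitializationError(SupercoolError, RuntimeError):
    """No starting point could be derived from the data and none was supplied."""


class NoTransitionError(SupercoolError, RuntimeError):
    """The sought physical feature (step, slope break, peak) is absent."""


class PipelineStageError(SupercoolError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
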