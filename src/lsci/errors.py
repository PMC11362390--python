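"""Exception hierarchy for the pipeline.

Errors are split by who can fix them: configuration errors (bad parameter
choices), usage errors (API misuse), data errors (a specific input file or
recording is unusable), and domain errors (mathematically invalid argument).
"""


class LsciError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LsciError):
    """A parameter or configuration value is invalid."""


class UsageError(LsciError):
    """An operation was called in a way that makes no sense (empty input, ...)."""


class DataError(LsciError):
    """A specific input (recording, ROI, placement) is unusable; names the offender."""


class DomainError(LsciError, ValueError):
    """A numeric argument is outside the mathematical domain of the function."""


class PipelineStageError(LsciError):
    """A pipeline stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
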