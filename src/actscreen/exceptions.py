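"""Exception hierarchy shared across the package."""


class ActScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(ActScreenError, ValueError):
    """Invalid configuration or parameter value."""


class SchemaError(ActScreenError, ValueError):
    """A gaze-log file does not have the expected columns."""


class ParseError(ActScreenError, ValueError):
    """A gaze-log file contains a cell that cannot be parsed."""


class StageOrderError(ActScreenError, RuntimeError):
    """A preprocessing stage was applied out of pipeline order."""


class UnrecoverableSampleError(ActScreenError, ValueError):
    """A sample lost all of its data during preprocessing and must be discarded."""


class PipelineStageError(ActScreenError, RuntimeError):
    """A named stage of an end-to-end run failed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
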