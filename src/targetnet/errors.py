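"""Exception hierarchy shared across pipeline stages."""


class TargetNetError(Exception):
    """Base class for all package errors."""


class EmptyResultError(TargetNetError):
    """A stage produced an empty result the downstream pipeline cannot consume."""


class EmptyNetworkError(TargetNetError):
    """Every edge was filtered out while building the interaction network."""


class StageError(TargetNetError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
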