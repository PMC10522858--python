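"""Exception hierarchy shared across the pipeline."""


class VnarpanError(Exception):
    """Base class for all package errors."""


class ParseError(VnarpanError):
    """A sequence file is malformed (bad record structure, duplicate id, ...)."""


class FormatError(VnarpanError):
    """A tabular artifact violates its format contract."""


class UndefinedStatisticError(VnarpanError):
    """A statistic was requested on input where it is mathematically undefined."""


class PipelineStageError(VnarpanError):
    """A pipeline stage failed; carries the stage name for the manifest."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
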