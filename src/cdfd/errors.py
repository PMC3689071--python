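"""Exception types shared across the pipeline."""


class CdfdError(Exception):
    """Base class for all package errors."""


class ParameterError(CdfdError, ValueError):
    """An argument violates a documented precondition."""


class DataFormatError(CdfdError, ValueError):
    """An input file or table is malformed."""


class DegenerateBaselineError(CdfdError):
    """A unit's baseline has zero variance; classification is refused."""


class PipelineError(CdfdError):
    """A pipeline stage failed; carries stage and unit context."""

    def __init__(self, stage: str, unit_id: str | None, message: str):
        self.stage = stage
        self.unit_id = unit_id
        detail = f"[{stage}]" + (f" unit {unit_id}:" if unit_id else "") + f" {message}"
        super().__init__(detail)
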