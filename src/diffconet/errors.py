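"""Exception hierarchy shared across the pipeline."""


class DiffconetError(Exception):
    """Base class for all package-specific errors."""


class InputError(DiffconetError, ValueError):
    """Malformed or inconsistent user input (files, tables, arguments)."""


class DegenerateDataError(DiffconetError, ValueError):
    """Data that leaves a statistic undefined (e.g. a probe set with no
    informative probes)."""


class DenominatorMismatchError(DiffconetError, ValueError):
    """A printed percentage is inconsistent with the stated group size."""


class PipelineStageError(DiffconetError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
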