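"""Exception hierarchy for sipnet.

All package-raised errors derive from :class:`SipnetError` so callers can
catch analysis failures without masking programming errors.
"""


class SipnetError(Exception):
    """Base class for all sipnet errors."""


class ConfigurationError(SipnetError):
    """Invalid simulation or pipeline configuration."""


class SelectionError(SipnetError):
    """No gradient fraction lies within tolerance of the target density."""


class DegenerateProfileError(SipnetError):
    """A gradient channel is flat, so a peak cannot be located."""


class EmptyInputError(SipnetError):
    """An operation received an empty table or vector."""


class GroupingError(SipnetError):
    """Sample groups overlap or reference unknown samples."""


class DegenerateInputError(SipnetError):
    """Input has no variance (or too few groups/samples) for the statistic."""


class PipelineStageError(SipnetError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
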