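"""Exception types shared across the package."""


class NeurovocError(Exception):
    """Base class for package errors."""


class InvalidRateError(NeurovocError, ValueError):
    """Sampling rate incompatible with the requested operation."""


class TooShortError(NeurovocError, ValueError):
    """Signal shorter than one analysis window."""


class DimensionError(NeurovocError, ValueError):
    """Array shapes do not match the operation's contract."""


class AlignmentError(NeurovocError, ValueError):
    """Paired streams disagree in duration by more than one frame."""


class MissingComponentError(NeurovocError, FileNotFoundError):
    """A session directory lacks a required component."""


class ConsistencyError(NeurovocError, ValueError):
    """Stored metadata disagrees between files of one session."""


class PipelineError(NeurovocError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
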