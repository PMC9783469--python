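"""Exception hierarchy.

Every error raised by the library derives from :class:`BrainbeatError` so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class BrainbeatError(Exception):
    """Base class for all brainbeat errors."""


class InvalidParameterError(BrainbeatError, ValueError):
    """A parameter violates a precondition (e.g. cutoff above Nyquist)."""


class TraceTooShortError(BrainbeatError, ValueError):
    """A physiological trace is too short for the requested operation."""


class CycleNotFoundError(BrainbeatError):
    """No autocorrelation peak inside the plausible heart-rate band."""


class InsufficientBeatsError(BrainbeatError):
    """Fewer heartbeat peaks than the operation requires."""


class InvalidGeometryError(BrainbeatError, ValueError):
    """Image/timing geometry mismatch (grid, slice count, volume count)."""


class ModelError(BrainbeatError):
    """Degenerate input to the waveform model (empty or rank-0 matrix)."""


class ConfigurationError(BrainbeatError, ValueError):
    """Inconsistent analysis configuration (e.g. held-out subject in training)."""


class PipelineError(BrainbeatError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
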