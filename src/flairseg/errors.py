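"""Exception hierarchy used across the pipeline.

Every failure mode named in the module contracts maps to one of these, so
callers (and the CLI exit-code mapping) can distinguish config mistakes,
bad data, and the classification gate.
"""


class FlairsegError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FlairsegError):
    """Invalid configuration value (bad scale divisor, missing mode input...)."""


class ValidationError(FlairsegError):
    """Input data violates a contract (shape mismatch, NaNs, mixed lengths)."""


class FormatError(FlairsegError):
    """A file exists but is not in the expected format."""


class BoundsError(FlairsegError, IndexError):
    """Index or window outside the valid range."""


class DegenerateInputError(FlairsegError):
    """Input is technically well-formed but the operation is undefined on it
    (constant image for z-scoring, 1-D grid for a 2-D gradient)."""


class DivergenceError(FlairsegError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class NoTumorDetected(FlairsegError):
    """The classification gate rejected the slice: nothing to segment.

    Deliberately an exception rather than an empty mask so that callers
    cannot silently confuse "no tumor" with "tumor of zero pixels".
    """
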