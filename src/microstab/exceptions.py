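"""Exception hierarchy for microstab.

Every error raised by the library derives from :class:`MicrostabError` so
callers can catch domain failures without masking programming errors.
"""


class MicrostabError(Exception):
    """Base class for all microstab errors."""


class DegenerateDesignError(MicrostabError):
    """Calibration design cannot support a line fit (too few distinct
    levels, or zero variance in the predictor)."""


class InvalidWeightingError(MicrostabError):
    """A 1/x or 1/x**2 weighting was requested for data containing
    non-positive concentrations."""


class NonInvertibleFitError(MicrostabError):
    """A calibration fit with zero slope cannot back-calculate."""


class InsufficientReplicatesError(MicrostabError):
    """Fewer replicates than the statistic requires (e.g. %RSD needs n >= 2)."""


class InputError(MicrostabError):
    """Malformed numeric input: empty groups, zero denominators, values
    outside their documented domain."""


class SchemaError(MicrostabError):
    """A CSV table does not match its declared schema."""


class NormalizationError(MicrostabError):
    """A depletion profile cannot be normalized to time zero (missing t=0
    row or non-positive t=0 concentration)."""


class SegmentError(MicrostabError):
    """The requested ln-linear window contains too few points."""


class LogDomainError(MicrostabError):
    """Non-positive percent-remaining inside the ln-linear window."""


class NoDepletionError(MicrostabError):
    """Slope is non-negative, so no half-life exists (negative-control
    behaviour)."""


class StageError(MicrostabError):
    """A study-pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
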