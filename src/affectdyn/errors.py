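"""Exception hierarchy for affectdyn.

All package errors derive from :class:`AffectDynError` so callers can catch
one base class at the CLI boundary.
"""


class AffectDynError(Exception):
    """Base class for all affectdyn errors."""


class FormatError(AffectDynError):
    """An input file violates the expected on-disk format."""


class InvalidInputError(AffectDynError):
    """An in-memory argument violates a precondition."""


class InvalidParameterError(AffectDynError):
    """A configuration parameter is out of its admissible range."""


class ScheduleError(AffectDynError):
    """A block schedule violates the session-design invariants."""


class OutOfRangeError(AffectDynError):
    """A requested time window lies outside the recorded signal."""


class DegenerateSegmentError(AffectDynError):
    """A signal segment has (near-)zero mean so the variability index is undefined."""


class NonNormalizableError(AffectDynError):
    """A row of raw variability indices is all zero and cannot be normalized."""


class ReducibleChainError(AffectDynError):
    """The transition matrix is reducible; no unique stationary distribution."""


class InvalidMatrixError(AffectDynError):
    """A matrix read from disk is too far from row-stochastic to repair."""


class ConsistencyError(AffectDynError):
    """Two inputs (signal and schedule) are mutually inconsistent."""


class PipelineError(AffectDynError):
    """A pipeline stage failed; carries the stage name and the original error."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
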