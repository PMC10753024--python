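"""Analysis configuration: the small set of tunables, with a stable hash.

Every knob the pipeline exposes lives here so a report can carry a single
config hash in its provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .errors import InvalidParameterError


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline settings.

    smooth_ms
        Width of the centred moving average applied after rectification when
        the input is a raw (signed) signal rather than an envelope.
    sd_ddof
        Delta degrees of freedom for the standard deviation in the delta
        index (1 = sample SD, the default small-sample convention).
    steady_steps
        Number of propagation steps defining the operational steady state.
    row_sum_tol
        Tolerated deviation of a row sum from 1 when reading a matrix CSV
        (printed matrices carry 2-dp rounding); offending rows are
        renormalized with a warning.
    screen_high / screen_low
        CFI/CFS mean-item-score thresholds for the high and low flexibility
        groups.
    """

    smooth_ms: float = 100.0
    sd_ddof: int = 1
    steady_steps: int = 5
    row_sum_tol: float = 0.02
    screen_high: float = 6.0
    screen_low: float = 3.0

    def __post_init__(self):
        if self.smooth_ms <= 0:
            raise InvalidParameterError("smooth_ms must be positive")
        if self.sd_ddof not in (0, 1):
            raise InvalidParameterError("sd_ddof must be 0 or 1")
        if self.steady_steps < 0:
            raise InvalidParameterError("steady_steps must be >= 0")
        if not 0 <= self.row_sum_tol < 0.5:
            raise InvalidParameterError("row_sum_tol must be in [0, 0.5)")
        if self.screen_low >= self.screen_high:
            raise InvalidParameterError("screen_low must be below screen_high")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls(**json.loads(text))

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_json(Path(path).read_text())

    def hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
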