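"""Published calibration matrices for the two illustrative participants.

These are the transition matrices reported for one very high-flexibility and
one very low-flexibility participant in the model's initial calibration
(corrugator supercilii f-EMG, 13-block affect-induction session).  Values are
as printed, at 2 decimal places; because of that rounding one row of the
low-flexibility matrix sums to 0.99 and is renormalized when converted to a
:class:`~affectdyn.markov.TransitionMatrix`.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError
from .markov import TransitionMatrix

# rows/cols ordered (Stress, Engagement, Boring, Relax); rows = from-state
HIGH_FLEXIBILITY_MATRIX = np.array(
    [
        [0.48, 0.17, 0.30, 0.05],
        [0.04, 0.48, 0.31, 0.17],
        [0.22, 0.12, 0.58, 0.08],
        [0.51, 0.04, 0.36, 0.09],
    ]
)

LOW_FLEXIBILITY_MATRIX = np.array(
    [
        [0.65, 0.12, 0.12, 0.11],
        [0.14, 0.50, 0.17, 0.18],  # printed row sums to 0.99 (2-dp rounding)
        [0.13, 0.13, 0.59, 0.15],
        [0.17, 0.21, 0.15, 0.47],
    ]
)

_RAW = {"high": HIGH_FLEXIBILITY_MATRIX, "low": LOW_FLEXIBILITY_MATRIX}


def reference_matrix_raw(flexibility: str) -> np.ndarray:
    """The printed matrix for the given phenotype, exactly as published."""
    try:
        return _RAW[flexibility].copy()
    except KeyError:
        raise InvalidInputError(
            f"flexibility must be 'high' or 'low', got {flexibility!r}"
        ) from None


def reference_matrix(flexibility: str) -> TransitionMatrix:
    """The published matrix as a row-stochastic TransitionMatrix.

    Rows are renormalized to absorb the 2-dp print rounding (at most 1% off).
    """
    raw = reference_matrix_raw(flexibility)
    return TransitionMatrix(values=raw / raw.sum(axis=1, keepdims=True))
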