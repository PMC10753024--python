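"""The delta/Delta Markov core: variability indices, transition matrix, steady states.

The model quantifies affect dynamics from a windowed physiological envelope in
four steps:

1. For every analysis window, the **delta index** — the coefficient of
   variation, sample standard deviation divided by the absolute mean — gives a
   dimensionless, scale-free measure of standardized variability (the
   reciprocal of the noise-to-signal ratio).
2. The 12 cross windows give one delta per ordered pair of distinct states;
   the 13 self windows, averaged per state over that state's 3-4 blocks, give
   the 4 self-state deltas: 16 indices in total.
3. Row-normalizing the 4x4 delta array yields the **Delta transition matrix**,
   a row-stochastic matrix where each entry is a transition's share of its
   row's total variability.
4. The distribution over states is propagated through the chain.  The model's
   operational "steady state" is the distribution after five steps from a
   uniform start; the exact eigenvector stationary distribution is exposed as
   a separate operation, since five steps only approximate it.

Source/receiver indices summarize the off-diagonal mass: the off-diagonal row
sum is a state's tendency to emit transitions (source), the off-diagonal
column sum its tendency to attract them (receiver).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg

from .design import ALL_TRANSITIONS, STATE_LABELS, STATE_ORDER, AffectiveState
from .errors import (
    DegenerateSegmentError,
    InvalidInputError,
    InvalidMatrixError,
    InvalidParameterError,
    NonNormalizableError,
    ReducibleChainError,
)
from .signal import EnvelopeSignal, TransitionWindowSet

N_STATES = 4
ROW_SUM_TOL = 1e-9
DEGENERATE_MEAN_TOL = 1e-12
READ_ROW_SUM_TOL = 0.02  # printed matrices carry 2-dp rounding


@dataclass(frozen=True)
class DeltaIndexSet:
    """The 16 raw delta indices keyed by ordered state pair (12 cross + 4 self)."""

    delta: Mapping[tuple[AffectiveState, AffectiveState], float]

    def __post_init__(self):
        expected = set(ALL_TRANSITIONS) | {(s, s) for s in STATE_ORDER}
        keys = set(self.delta.keys())
        if keys != expected:
            raise InvalidInputError(
                f"delta set must contain exactly the 16 ordered state pairs; "
                f"missing {expected - keys}, unexpected {keys - expected}"
            )
        for pair, value in self.delta.items():
            if not np.isfinite(value) or value < 0:
                raise InvalidInputError(
                    f"delta[{pair[0].label}->{pair[1].label}] must be finite and "
                    f">= 0, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        """Raw 4x4 delta array in fixed state order (rows = from, cols = to)."""
        arr = np.empty((N_STATES, N_STATES))
        for i in STATE_ORDER:
            for j in STATE_ORDER:
                arr[int(i), int(j)] = self.delta[(i, j)]
        return arr

    def __getitem__(self, pair: tuple[AffectiveState, AffectiveState]) -> float:
        return self.delta[pair]


@dataclass(frozen=True)
class TransitionMatrix:
    """A 4x4 row-stochastic matrix over (Stress, Engagement, Boring, Relax)."""

    values: np.ndarray
    state_order: tuple[AffectiveState, ...] = STATE_ORDER

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (N_STATES, N_STATES):
            raise InvalidInputError(f"transition matrix must be 4x4, got {values.shape}")
        if np.any(values < -ROW_SUM_TOL) or not np.all(np.isfinite(values)):
            raise InvalidInputError("transition matrix entries must be finite and >= 0")
        row_sums = values.sum(axis=1)
        if np.max(np.abs(row_sums - 1.0)) > ROW_SUM_TOL:
            raise InvalidInputError(
                f"transition matrix rows must sum to 1 within {ROW_SUM_TOL}; "
                f"row sums are {row_sums}"
            )

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.values[int(i), int(j)])


@dataclass(frozen=True)
class StateDistribution:
    """A probability vector over the four states after ``step`` propagation steps."""

    probs: np.ndarray
    step: int = 0

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (N_STATES,):
            raise InvalidInputError(f"distribution must have 4 components, got {probs.shape}")
        if np.any(probs < -ROW_SUM_TOL) or not np.all(np.isfinite(probs)):
            raise InvalidInputError("probabilities must be finite and >= 0")
        if abs(probs.sum() - 1.0) > ROW_SUM_TOL:
            raise InvalidInputError(f"probabilities must sum to 1, got {probs.sum()!r}")
        if self.step < 0:
            raise InvalidParameterError("step must be >= 0")

    def __getitem__(self, state) -> float:
        return float(self.probs[int(state)])


def uniform_distribution() -> StateDistribution:
    return StateDistribution(probs=np.full(N_STATES, 1.0 / N_STATES), step=0)


# ---------------------------------------------------------------------------
# delta indices

def delta_index(segment: np.ndarray, ddof: int = 1) -> float:
    """Standardized variability of a segment: sample SD / |mean|.

    This is the coefficient of variation — the reciprocal of the
    signal-to-noise ratio — so it is dimensionless and invariant under
    positive rescaling of the signal.  ``ddof=1`` (sample SD) by default.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1 or len(segment) < 2:
        raise InvalidInputError("delta index needs a 1-D segment of length >= 2")
    mean = segment.mean()
    if abs(mean) <= DEGENERATE_MEAN_TOL:
        raise DegenerateSegmentError(
            f"segment mean {mean!r} is too close to zero for a variability ratio"
        )
    return float(segment.std(ddof=ddof) / abs(mean))


def assemble_delta_matrix(
    windows: TransitionWindowSet, signal: EnvelopeSignal, ddof: int = 1
) -> DeltaIndexSet:
    """Compute all 16 delta indices of a session.

    Each ordered distinct pair takes the delta of its unique cross window;
    each self-state delta is the arithmetic mean of the per-block deltas over
    that state's blocks.
    """
    delta: dict[tuple[AffectiveState, AffectiveState], float] = {}
    for w in windows.cross_windows:
        try:
            delta[(w.from_state, w.to_state)] = delta_index(
                signal.slice(w.start_s, w.end_s), ddof=ddof
            )
        except DegenerateSegmentError as err:
            raise DegenerateSegmentError(
                f"cross window {w.from_state.label}->{w.to_state.label} "
                f"[{w.start_s}, {w.end_s}) s: {err}"
            ) from err

    per_state: dict[AffectiveState, list[float]] = {s: [] for s in STATE_ORDER}
    for w in windows.self_windows:
        try:
            per_state[w.state].append(
                delta_index(signal.slice(w.start_s, w.end_s), ddof=ddof)
            )
        except DegenerateSegmentError as err:
            raise DegenerateSegmentError(
                f"self window block {w.block_index} ({w.state.label}) "
                f"[{w.start_s}, {w.end_s}) s: {err}"
            ) from err
    for s, values in per_state.items():
        delta[(s, s)] = float(np.mean(values))
    return DeltaIndexSet(delta=delta)


# ---------------------------------------------------------------------------
# matrix assembly and propagation

def normalize_rows(delta: DeltaIndexSet | np.ndarray) -> TransitionMatrix:
    """Row-normalize raw delta indices into the Delta transition matrix.

    Delta[i, j] = delta[i, j] / sum_j delta[i, j]: each entry is the share of
    row i's total variability carried by the transition to j.
    """
    arr = delta.as_array() if isinstance(delta, DeltaIndexSet) else np.asarray(delta, float)
    row_sums = arr.sum(axis=1)
    for i, total in enumerate(row_sums):
        if total <= 0:
            raise NonNormalizableError(
                f"row {STATE_LABELS[i]} has zero total variability and cannot "
                f"be normalized"
            )
    return TransitionMatrix(values=arr / row_sums[:, None])


def propagate(
    matrix: TransitionMatrix, s0: StateDistribution, k: int
) -> StateDistribution:
    """k-step propagation: the row vector s0 times the k-th matrix power."""
    if k < 0:
        raise InvalidParameterError(f"number of steps must be >= 0, got {k}")
    probs = s0.probs @ np.linalg.matrix_power(matrix.values, k)
    return StateDistribution(probs=probs, step=k)


def steady_state(
    matrix: TransitionMatrix,
    steps: int = 5,
    s0: StateDistribution | None = None,
) -> StateDistribution:
    """The model's operational steady state: 5-step propagation from uniform.

    This is a finite-horizon summary, not the asymptotic stationary
    distribution; see :func:`eigen_stationary` for the exact limit.
    """
    if s0 is None:
        s0 = uniform_distribution()
    return propagate(matrix, s0, steps)


def is_irreducible(matrix: TransitionMatrix) -> bool:
    """Irreducibility of the chain = strong connectivity of its positive-edge digraph."""
    g = nx.DiGraph()
    g.add_nodes_from(range(N_STATES))
    rows, cols = np.nonzero(matrix.values > 0)
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return nx.is_strongly_connected(g)


def eigen_stationary(matrix: TransitionMatrix) -> StateDistribution:
    """The exact stationary distribution pi with pi P = pi.

    Solved as the null space of (P^T - I) after verifying irreducibility on
    the embedded digraph.  The residual ||pi P - pi||_inf is checked against
    1e-10.
    """
    if not is_irreducible(matrix):
        raise ReducibleChainError(
            "transition matrix is reducible: no unique stationary distribution"
        )
    ns = linalg.null_space(matrix.values.T - np.eye(N_STATES))
    if ns.shape[1] != 1:
        raise ReducibleChainError(
            f"stationary subspace has dimension {ns.shape[1]}, expected 1"
        )
    pi = ns[:, 0]
    pi = np.abs(pi) / np.abs(pi).sum()
    residual = np.max(np.abs(pi @ matrix.values - pi))
    if residual > 1e-10:
        raise ReducibleChainError(f"stationary residual {residual} exceeds 1e-10")
    return StateDistribution(probs=pi, step=0)


def source_receiver(
    matrix: TransitionMatrix,
) -> dict[AffectiveState, tuple[float, float]]:
    """Per-state (source, receiver) indices from the off-diagonal mass.

    source(i) = off-diagonal row sum = 1 - Delta[i, i]: how strongly state i
    emits transitions.  receiver(j) = off-diagonal column sum: how strongly
    state j attracts them.
    """
    values = matrix.values
    off = values - np.diag(np.diag(values))
    sources = off.sum(axis=1)
    receivers = off.sum(axis=0)
    return {
        s: (float(sources[int(s)]), float(receivers[int(s)])) for s in STATE_ORDER
    }


# ---------------------------------------------------------------------------
# matrix I/O

def write_matrix_csv(values: np.ndarray | TransitionMatrix, path: str | Path) -> None:
    """Write a 4x4 matrix as CSV with state labels on both axes."""
    if isinstance(values, TransitionMatrix):
        values = values.values
    df = pd.DataFrame(np.asarray(values, float), index=STATE_LABELS, columns=STATE_LABELS)
    df.to_csv(path, index_label="state")


def load_matrix_csv(path: str | Path) -> np.ndarray:
    """Read a labelled 4x4 matrix CSV back to a raw array (no normalization)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.columns) != list(STATE_LABELS) or list(df.index) != list(STATE_LABELS):
        raise InvalidMatrixError(
            f"matrix CSV must be labelled {STATE_LABELS} on both axes"
        )
    return df.to_numpy(dtype=float)


def read_transition_matrix(
    path: str | Path, row_sum_tol: float = READ_ROW_SUM_TOL
) -> tuple[TransitionMatrix, list[str]]:
    """Tolerant read of a transition-matrix CSV.

    Published matrices are printed at 2 decimal places, so a row may sum to
    e.g. 0.99.  Rows within ``row_sum_tol`` of 1 are renormalized, and each
    repair is reported in the returned warning list; a larger deviation raises
    :class:`InvalidMatrixError`.
    """
    arr = load_matrix_csv(path)
    warnings: list[str] = []
    row_sums = arr.sum(axis=1)
    for i, total in enumerate(row_sums):
        if abs(total - 1.0) > row_sum_tol:
            raise InvalidMatrixError(
                f"row {STATE_LABELS[i]} sums to {total:.4f}, off by more than "
                f"{row_sum_tol}"
            )
        if abs(total - 1.0) > ROW_SUM_TOL:
            warnings.append(
                f"row {STATE_LABELS[i]} summed to {total:.4f}; renormalized"
            )
    return TransitionMatrix(values=arr / row_sums[:, None]), warnings


def to_dot(matrix: TransitionMatrix, name: str = "transitions") -> str:
    """Render the chain as a DOT weighted digraph (edge label = probability)."""
    lines = [f"digraph {name} {{", "  rankdir=LR;"]
    for s in STATE_ORDER:
        lines.append(f'  {s.label};')
    for i in STATE_ORDER:
        for j in STATE_ORDER:
            w = matrix[i, j]
            if w > 0:
                lines.append(
                    f'  {i.label} -> {j.label} [label="{w:.2f}", weight={w:.4f}];'
                )
    lines.append("}")
    return "\n".join(lines)
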