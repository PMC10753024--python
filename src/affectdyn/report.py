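"""The end-to-end analysis pipeline and its serializable report.

``run_pipeline`` chains the stages load -> window -> delta -> Delta ->
steady state -> source/receiver and packages the results, with provenance,
into an :class:`AnalysisReport` that round-trips through JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import AnalysisConfig
from .design import (
    STATE_ORDER,
    AffectiveState,
    BlockSchedule,
    FlexibilityScreen,
    read_schedule_csv,
)
from .errors import ConsistencyError, PipelineError, ReducibleChainError
from .markov import (
    DeltaIndexSet,
    StateDistribution,
    TransitionMatrix,
    assemble_delta_matrix,
    eigen_stationary,
    normalize_rows,
    source_receiver,
    steady_state,
)
from .signal import EnvelopeSignal, extract_windows, load_signal, make_envelope

logger = logging.getLogger("affectdyn")


@dataclass(frozen=True)
class AnalysisReport:
    """All outputs of one subject's session analysis, plus provenance."""

    subject_id: str
    screen: FlexibilityScreen | None
    delta: DeltaIndexSet
    matrix: TransitionMatrix
    steady_5step: StateDistribution
    eigen_stationary: StateDistribution | None
    source_receiver: dict[AffectiveState, tuple[float, float]]
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "subject_id": self.subject_id,
            "screen": (
                None
                if self.screen is None
                else {
                    "cfi_score": self.screen.cfi_score,
                    "cfs_score": self.screen.cfs_score,
                    "group": self.screen.group,
                }
            ),
            "delta": {
                f"{i.label}->{j.label}": self.delta[(i, j)]
                for i in STATE_ORDER
                for j in STATE_ORDER
            },
            "matrix": self.matrix.values.tolist(),
            "steady_5step": {
                "probs": self.steady_5step.probs.tolist(),
                "step": self.steady_5step.step,
            },
            "eigen_stationary": (
                None
                if self.eigen_stationary is None
                else self.eigen_stationary.probs.tolist()
            ),
            "source_receiver": {
                s.label: list(self.source_receiver[s]) for s in STATE_ORDER
            },
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        payload = json.loads(text)
        screen = payload["screen"]
        delta = {
            (AffectiveState.from_label(k.split("->")[0]),
             AffectiveState.from_label(k.split("->")[1])): v
            for k, v in payload["delta"].items()
        }
        eig = payload["eigen_stationary"]
        return cls(
            subject_id=payload["subject_id"],
            screen=None if screen is None else FlexibilityScreen(**screen),
            delta=DeltaIndexSet(delta=delta),
            matrix=TransitionMatrix(values=np.array(payload["matrix"])),
            steady_5step=StateDistribution(
                probs=np.array(payload["steady_5step"]["probs"]),
                step=payload["steady_5step"]["step"],
            ),
            eigen_stationary=(
                None if eig is None else StateDistribution(probs=np.array(eig))
            ),
            source_receiver={
                AffectiveState.from_label(k): (v[0], v[1])
                for k, v in payload["source_receiver"].items()
            },
            provenance=payload["provenance"],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnalysisReport):
            return NotImplemented
        return json.loads(self.to_json()) == json.loads(other.to_json())


def run_pipeline(
    signal_path: str | Path,
    schedule_path: str | Path,
    config: AnalysisConfig | None = None,
    subject_id: str = "anonymous",
    screen: FlexibilityScreen | None = None,
    envelope: bool = True,
    seed: int | None = None,
) -> AnalysisReport:
    """Run the full analysis on a recorded (or simulated) session.

    Stage failures are re-raised as :class:`PipelineError` carrying the stage
    name; the offending window or state is named by the underlying error.
    """
    config = config or AnalysisConfig()

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as err:
            raise PipelineError(name, err) from err

    schedule: BlockSchedule = stage("load_schedule", lambda: read_schedule_csv(schedule_path))
    signal: EnvelopeSignal = stage(
        "load_signal", lambda: load_signal(signal_path, envelope=envelope)
    )
    if not envelope:
        signal = stage(
            "make_envelope",
            lambda: make_envelope(
                signal.samples,
                signal.sampling_rate,
                smooth_ms=config.smooth_ms,
                t0=signal.t0,
            ),
        )

    # tolerate one sample period of float slack from time-column round-trips
    if signal.t0 + signal.duration_s < schedule.span_s - 1.0 / signal.sampling_rate:
        raise PipelineError(
            "consistency",
            ConsistencyError(
                f"signal span {signal.duration_s:.1f} s is shorter than the "
                f"schedule span {schedule.span_s:.1f} s"
            ),
        )

    windows = stage("extract_windows", lambda: extract_windows(schedule))
    for w in windows.all_windows():
        logger.info("window %s: [%.1f, %.1f) s", w, w.start_s, w.end_s)
    delta = stage(
        "delta_indices",
        lambda: assemble_delta_matrix(windows, signal, ddof=config.sd_ddof),
    )
    for pair, value in delta.delta.items():
        logger.info("delta %s->%s = %.4f", pair[0].label, pair[1].label, value)
    matrix = stage("normalize", lambda: normalize_rows(delta))
    steady = stage(
        "steady_state", lambda: steady_state(matrix, steps=config.steady_steps)
    )
    try:
        eig = eigen_stationary(matrix)
    except ReducibleChainError as err:
        logger.warning("no unique stationary distribution: %s", err)
        eig = None
    sr = stage("source_receiver", lambda: source_receiver(matrix))

    provenance = {
        "signal_path": str(signal_path),
        "schedule_path": str(schedule_path),
        "seed": seed,
        "config_hash": config.hash(),
        "tool_version": __version__,
    }
    return AnalysisReport(
        subject_id=subject_id,
        screen=screen,
        delta=delta,
        matrix=matrix,
        steady_5step=steady,
        eigen_stationary=eig,
        source_receiver=sr,
        provenance=provenance,
    )
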