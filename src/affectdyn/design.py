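"""Session design: affective states, the 13-block schedule, participant screening.

The affect-induction session walks a participant through the four quadrants of
the valence-arousal circumplex (Stress, Engagement, Boring, Relax) using 13
picture blocks of 120 s each.  Because the analysis needs one sample of every
ordered transition between distinct states, the block sequence is an Eulerian
circuit on the complete 4-vertex digraph: 12 directed edges, hence 12 block
boundaries, hence 13 blocks.  The circuit starts and ends on the same state,
so one state occurs in 4 blocks and the other three in 3 blocks each.

Participants are screened into flexibility groups from the mean item scores of
two self-report instruments, the Cognitive Flexibility Inventory (CFI) and the
Cognitive Flexibility Scale (CFS): both above 6 is *high*, both below 3 is
*low*, anything else is *intermediate*.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError, ScheduleError

BLOCK_DURATION_S = 120.0
N_BLOCKS = 13
IMAGES_PER_BLOCK = 12
SECONDS_PER_IMAGE = 10.0
SESSION_SPAN_S = N_BLOCKS * BLOCK_DURATION_S  # 1560 s

CFI_CFS_HIGH_THRESHOLD = 6.0
CFI_CFS_LOW_THRESHOLD = 3.0


class AffectiveState(enum.IntEnum):
    """The four circumplex-quadrant states, in fixed matrix order."""

    STRESS = 0
    ENGAGEMENT = 1
    BORING = 2
    RELAX = 3

    @property
    def label(self) -> str:
        return self.name.capitalize()

    @classmethod
    def from_label(cls, label: str) -> "AffectiveState":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise InvalidInputError(f"unknown affective state label: {label!r}") from None


STATE_ORDER: tuple[AffectiveState, ...] = tuple(AffectiveState)
STATE_LABELS: tuple[str, ...] = tuple(s.label for s in STATE_ORDER)

#: The 12 ordered pairs of distinct states = edges of the complete 4-vertex digraph.
ALL_TRANSITIONS: tuple[tuple[AffectiveState, AffectiveState], ...] = tuple(
    (a, b) for a in STATE_ORDER for b in STATE_ORDER if a != b
)


@dataclass(frozen=True)
class Block:
    state: AffectiveState
    onset_s: float
    duration_s: float = BLOCK_DURATION_S


@dataclass(frozen=True)
class BlockSchedule:
    """An ordered 13-block session defining the 12 analysed transitions."""

    blocks: tuple[Block, ...]
    images_per_block: int = IMAGES_PER_BLOCK
    seconds_per_image: float = SECONDS_PER_IMAGE

    @property
    def span_s(self) -> float:
        last = self.blocks[-1]
        return last.onset_s + last.duration_s

    @property
    def states(self) -> tuple[AffectiveState, ...]:
        return tuple(b.state for b in self.blocks)

    def transitions(self) -> tuple[tuple[AffectiveState, AffectiveState], ...]:
        """Consecutive (from, to) state pairs at the 12 block boundaries."""
        s = self.states
        return tuple(zip(s[:-1], s[1:]))

    def boundaries(self) -> tuple[float, ...]:
        """Times (s) of the block boundaries, excluding session start and end."""
        return tuple(b.onset_s for b in self.blocks[1:])


@dataclass(frozen=True)
class FlexibilityScreen:
    """Group assignment from CFI/CFS mean item scores."""

    cfi_score: float
    cfs_score: float
    group: str


@dataclass
class ScheduleValidation:
    """Pass/fail report for every schedule invariant."""

    checks: dict[str, tuple[bool, str]] = field(default_factory=dict)

    def record(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks[name] = (passed, detail)

    @property
    def ok(self) -> bool:
        return all(passed for passed, _ in self.checks.values())

    def failures(self) -> dict[str, str]:
        return {k: d for k, (p, d) in self.checks.items() if not p}


def generate_block_sequence(seed: int) -> BlockSchedule:
    """Generate a randomized 13-block schedule covering all 12 transitions once.

    The sequence is a uniformly seeded Eulerian circuit on the complete
    4-state digraph, found with a randomized Hierholzer traversal.  The same
    seed always yields the identical schedule.
    """
    rng = np.random.default_rng(seed)
    # unused out-edges per vertex, pre-shuffled so popping is random but seeded
    out_edges: dict[AffectiveState, list[AffectiveState]] = {}
    for v in STATE_ORDER:
        targets = [w for w in STATE_ORDER if w != v]
        rng.shuffle(targets)
        out_edges[v] = targets
    start = STATE_ORDER[int(rng.integers(len(STATE_ORDER)))]

    # Hierholzer: stack-based traversal consuming every edge exactly once
    stack: list[AffectiveState] = [start]
    circuit: list[AffectiveState] = []
    while stack:
        v = stack[-1]
        if out_edges[v]:
            stack.append(out_edges[v].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()

    blocks = tuple(
        Block(state=s, onset_s=i * BLOCK_DURATION_S) for i, s in enumerate(circuit)
    )
    return BlockSchedule(blocks=blocks)


def validate_schedule(schedule: BlockSchedule) -> ScheduleValidation:
    """Check every schedule invariant; failures are reported, not raised."""
    report = ScheduleValidation()
    n = len(schedule.blocks)
    report.record("block_count", n == N_BLOCKS, f"expected {N_BLOCKS} blocks, got {n}")

    durations_ok = all(
        math.isclose(b.duration_s, BLOCK_DURATION_S, abs_tol=1e-9) for b in schedule.blocks
    )
    report.record("durations", durations_ok, f"every block must last {BLOCK_DURATION_S} s")

    contiguous = all(
        math.isclose(b.onset_s, i * BLOCK_DURATION_S, abs_tol=1e-9)
        for i, b in enumerate(schedule.blocks)
    )
    report.record("contiguity", contiguous, "block b must start at 120*b seconds")

    observed = sorted((int(a), int(b)) for a, b in schedule.transitions())
    expected = sorted((int(a), int(b)) for a, b in ALL_TRANSITIONS)
    report.record(
        "transition_coverage",
        observed == expected,
        "the 12 boundaries must cover each ordered distinct-state pair exactly once",
    )

    report.record(
        "image_timing",
        math.isclose(
            schedule.images_per_block * schedule.seconds_per_image,
            BLOCK_DURATION_S,
            abs_tol=1e-9,
        ),
        "images_per_block * seconds_per_image must equal the block duration",
    )
    return report


def screen_flexibility(cfi: float, cfs: float) -> FlexibilityScreen:
    """Assign the flexibility group from CFI and CFS mean item scores.

    Both scores > 6 -> 'high'; both < 3 -> 'low'; otherwise 'intermediate'.
    """
    for name, score in (("cfi", cfi), ("cfs", cfs)):
        if not math.isfinite(score):
            raise InvalidInputError(f"{name} score must be finite, got {score!r}")
        if score < 0:
            raise InvalidInputError(f"{name} score must be nonnegative, got {score!r}")
    if cfi > CFI_CFS_HIGH_THRESHOLD and cfs > CFI_CFS_HIGH_THRESHOLD:
        group = "high"
    elif cfi < CFI_CFS_LOW_THRESHOLD and cfs < CFI_CFS_LOW_THRESHOLD:
        group = "low"
    else:
        group = "intermediate"
    return FlexibilityScreen(cfi_score=float(cfi), cfs_score=float(cfs), group=group)


# ---------------------------------------------------------------------------
# schedule I/O: CSV with header block,state,onset_s,duration_s and JSON mirror

def write_schedule_csv(schedule: BlockSchedule, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "block": range(len(schedule.blocks)),
            "state": [b.state.label for b in schedule.blocks],
            "onset_s": [b.onset_s for b in schedule.blocks],
            "duration_s": [b.duration_s for b in schedule.blocks],
        }
    )
    df.to_csv(path, index=False)


def read_schedule_csv(path: str | Path) -> BlockSchedule:
    df = pd.read_csv(path)
    required = {"block", "state", "onset_s", "duration_s"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"schedule CSV missing columns: {sorted(missing)}")
    df = df.sort_values("block")
    blocks = tuple(
        Block(
            state=AffectiveState.from_label(row.state),
            onset_s=float(row.onset_s),
            duration_s=float(row.duration_s),
        )
        for row in df.itertuples()
    )
    return BlockSchedule(blocks=blocks)


def write_schedule_json(schedule: BlockSchedule, path: str | Path) -> None:
    payload = {
        "images_per_block": schedule.images_per_block,
        "seconds_per_image": schedule.seconds_per_image,
        "blocks": [
            {
                "block": i,
                "state": b.state.label,
                "onset_s": b.onset_s,
                "duration_s": b.duration_s,
            }
            for i, b in enumerate(schedule.blocks)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_schedule_json(path: str | Path) -> BlockSchedule:
    payload = json.loads(Path(path).read_text())
    blocks = tuple(
        Block(
            state=AffectiveState.from_label(b["state"]),
            onset_s=float(b["onset_s"]),
            duration_s=float(b["duration_s"]),
        )
        for b in sorted(payload["blocks"], key=lambda b: b["block"])
    )
    return BlockSchedule(
        blocks=blocks,
        images_per_block=int(payload.get("images_per_block", IMAGES_PER_BLOCK)),
        seconds_per_image=float(payload.get("seconds_per_image", SECONDS_PER_IMAGE)),
    )
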