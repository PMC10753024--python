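"""Physiological signal ingest, envelope extraction, and analysis windows.

The variability analysis works on a nonnegative amplitude envelope (for the
calibration protocol: the corrugator supercilii facial-EMG envelope, a
physiological proxy of negative valence).  Two families of 30-s analysis
windows are cut from the session:

* *cross* windows — one per block boundary, centred on it (boundary +/- 15 s),
  capturing the transition between two distinct affective states;
* *self* windows — the middle 30 s of every block (onset + 45 s to + 75 s),
  capturing the sustained state away from both adjacent transitions.

Windows are half-open in time, [start, end), and a sample at time t belongs to
index floor((t - t0) * fs); this makes adjacent windows partition the samples
with no double counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import AffectiveState, BlockSchedule, validate_schedule
from .errors import (
    FormatError,
    InvalidParameterError,
    OutOfRangeError,
    ScheduleError,
)

CROSS_HALF_WIDTH_S = 15.0   # cross window = boundary +/- 15 s
SELF_WINDOW_START_S = 45.0  # self window = [onset+45, onset+75)
SELF_WINDOW_END_S = 75.0
TIME_STEP_TOL_S = 1e-6

_EPS = 1e-9  # guards float round-off when mapping times to sample indices


@dataclass(frozen=True)
class EnvelopeSignal:
    """A uniformly sampled nonnegative amplitude series on the schedule clock."""

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    channel_name: str = "corrugator_emg_envelope"

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise FormatError("signal samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise FormatError("signal contains non-finite samples")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.sampling_rate

    def slice(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples in the half-open window [start_s, end_s)."""
        if end_s <= start_s:
            raise OutOfRangeError(f"empty window [{start_s}, {end_s})")
        fs = self.sampling_rate
        i0 = int(np.floor((start_s - self.t0) * fs + _EPS))
        i1 = int(np.floor((end_s - self.t0) * fs + _EPS))
        if i0 < 0 or i1 > len(self.samples):
            raise OutOfRangeError(
                f"window [{start_s}, {end_s}) s outside recording "
                f"[{self.t0}, {self.t0 + self.duration_s}) s"
            )
        return self.samples[i0:i1]


@dataclass(frozen=True)
class CrossWindow:
    from_state: AffectiveState
    to_state: AffectiveState
    start_s: float
    end_s: float


@dataclass(frozen=True)
class SelfWindow:
    state: AffectiveState
    block_index: int
    start_s: float
    end_s: float


@dataclass(frozen=True)
class TransitionWindowSet:
    """The 12 cross-transition and 13 self-state analysis windows of a session."""

    cross_windows: tuple[CrossWindow, ...]
    self_windows: tuple[SelfWindow, ...]

    def all_windows(self) -> tuple:
        return self.cross_windows + self.self_windows


def load_signal(
    path: str | Path,
    sampling_rate: float | None = None,
    envelope: bool = True,
) -> EnvelopeSignal:
    """Read a `time_s,amplitude` CSV into an :class:`EnvelopeSignal`.

    The time column must be strictly increasing with a constant step (within
    1e-6 s).  The sampling rate is inferred from the time step; if
    ``sampling_rate`` is also given the two must agree.  With ``envelope=True``
    (the default) negative amplitudes are rejected, since the variability
    index is only meaningful on a nonnegative envelope.
    """
    df = pd.read_csv(path)
    missing = {"time_s", "amplitude"} - set(df.columns)
    if missing:
        raise FormatError(f"signal CSV missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    x = df["amplitude"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("signal CSV must contain at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise FormatError("time_s must be strictly increasing")
    step = np.median(steps)
    if np.max(np.abs(steps - step)) > TIME_STEP_TOL_S:
        raise FormatError(
            f"non-uniform sampling: time step deviates by more than {TIME_STEP_TOL_S} s"
        )
    inferred_fs = 1.0 / step
    if sampling_rate is not None and not np.isclose(
        sampling_rate, inferred_fs, rtol=1e-6
    ):
        raise FormatError(
            f"declared sampling rate {sampling_rate} Hz does not match the "
            f"time column ({inferred_fs:.6g} Hz)"
        )
    if envelope and np.any(x < 0):
        raise FormatError("negative amplitudes in a signal declared as an envelope")
    return EnvelopeSignal(samples=x, sampling_rate=float(inferred_fs), t0=float(t[0]))


def make_envelope(
    raw: np.ndarray,
    sampling_rate: float,
    smooth_ms: float = 100.0,
    t0: float = 0.0,
    channel_name: str = "envelope",
) -> EnvelopeSignal:
    """Full-wave rectification followed by a centred moving average.

    The moving average is edge-corrected (each output sample divides by the
    number of in-range input samples), so a constant input gives exactly a
    constant output.  ``smooth_ms`` must cover at least two sample periods.
    """
    raw = np.asarray(raw, dtype=float)
    if smooth_ms <= 0:
        raise InvalidParameterError("smooth_ms must be positive")
    width = int(round(smooth_ms / 1000.0 * sampling_rate))
    if width < 2:
        raise InvalidParameterError(
            f"smooth_ms={smooth_ms} is shorter than 2 sample periods at "
            f"{sampling_rate} Hz"
        )
    rect = np.abs(raw)
    kernel = np.ones(width)
    smoothed = np.convolve(rect, kernel, mode="same")
    norm = np.convolve(np.ones_like(rect), kernel, mode="same")
    return EnvelopeSignal(
        samples=smoothed / norm,
        sampling_rate=sampling_rate,
        t0=t0,
        channel_name=channel_name,
    )


def extract_windows(schedule: BlockSchedule) -> TransitionWindowSet:
    """Cut the 12 cross and 13 self analysis windows from a valid schedule."""
    report = validate_schedule(schedule)
    if not report.ok:
        raise ScheduleError(f"invalid schedule: {report.failures()}")

    cross = tuple(
        CrossWindow(
            from_state=frm,
            to_state=to,
            start_s=boundary - CROSS_HALF_WIDTH_S,
            end_s=boundary + CROSS_HALF_WIDTH_S,
        )
        for (frm, to), boundary in zip(schedule.transitions(), schedule.boundaries())
    )
    self_ = tuple(
        SelfWindow(
            state=b.state,
            block_index=i,
            start_s=b.onset_s + SELF_WINDOW_START_S,
            end_s=b.onset_s + SELF_WINDOW_END_S,
        )
        for i, b in enumerate(schedule.blocks)
    )
    return TransitionWindowSet(cross_windows=cross, self_windows=self_)


def write_windows_csv(windows: TransitionWindowSet, path: str | Path) -> None:
    rows = [
        {
            "kind": "cross",
            "from_state": w.from_state.label,
            "to_state": w.to_state.label,
            "block": "",
            "start_s": w.start_s,
            "end_s": w.end_s,
        }
        for w in windows.cross_windows
    ] + [
        {
            "kind": "self",
            "from_state": w.state.label,
            "to_state": w.state.label,
            "block": w.block_index,
            "start_s": w.start_s,
            "end_s": w.end_s,
        }
        for w in windows.self_windows
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_signal_csv(signal: EnvelopeSignal, path: str | Path) -> None:
    pd.DataFrame({"time_s": signal.times, "amplitude": signal.samples}).to_csv(
        path, index=False
    )
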