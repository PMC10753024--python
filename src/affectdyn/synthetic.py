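"""Synthetic session generator with prescribed per-window variability.

The simulator stands in for a real affect-induction recording: it emits a
nonnegative envelope over the full 1560-s session (13 blocks of 120 s at
100 Hz by default) in which every analysis window — the 12 cross-transition
windows and the 13 self-state windows — carries a prescribed coefficient of
variation (the target delta index).

Noise model
-----------
Within a window, samples are i.i.d. from a zero-truncated normal whose
*post-truncation* mean equals the window's base amplitude and whose
post-truncation SD equals ``target_delta * mean``.  The parent (pre-truncation)
parameters are solved by moment matching, so the realized coefficient of
variation is an unbiased estimate of the prescribed delta.  A zero-truncated
normal cannot exceed a CV of 1; targets at or beyond ~0.99 fall back to the
naive parametrization and are flagged.  A target so large that zero-truncation
of a normal with those moments would shift its mean by more than 10% is
recorded as an infeasibility warning (the run proceeds).

Between analysis windows the signal ramps linearly from one window's mean
amplitude to the next; only the analysis windows carry contract guarantees,
so the filler is chosen purely for continuity.

Phenotypes
----------
``make_phenotype`` builds specs whose target deltas equal the published
high- or low-flexibility calibration matrix entries, so the full pipeline can
be exercised end-to-end against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .design import (
    BlockSchedule,
    STATE_ORDER,
    AffectiveState,
    generate_block_sequence,
)
from .errors import InvalidParameterError
from .markov import DeltaIndexSet
from .reference import reference_matrix_raw
from .signal import EnvelopeSignal, TransitionWindowSet, extract_windows

#: Default per-state base amplitude of the simulated corrugator envelope, in
#: microvolts.  Corrugator activity rises with negative valence, so the two
#: negative-valence states sit higher than the positive ones.
DEFAULT_BASE_MEAN: dict[AffectiveState, float] = {
    AffectiveState.STRESS: 12.0,
    AffectiveState.ENGAGEMENT: 6.0,
    AffectiveState.BORING: 8.0,
    AffectiveState.RELAX: 4.0,
}

DEFAULT_SAMPLING_RATE = 100.0
MEAN_SHIFT_WARN_FRACTION = 0.10
_CV_FEASIBLE_MAX = 0.99  # zero-truncated normal CV is bounded above by 1


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to simulate one session deterministically."""

    schedule: BlockSchedule
    target_delta: DeltaIndexSet
    base_mean: dict[AffectiveState, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_MEAN)
    )
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate < 10.0:
            raise InvalidParameterError(
                f"sampling_rate must be >= 10 Hz, got {self.sampling_rate}"
            )
        for s in STATE_ORDER:
            if s not in self.base_mean or self.base_mean[s] <= 0:
                raise InvalidParameterError(
                    f"base_mean must be positive for every state; bad entry for "
                    f"{s.label}"
                )


@dataclass(frozen=True)
class SimulationResult:
    signal: EnvelopeSignal
    windows: TransitionWindowSet
    warnings: tuple[str, ...]


def _truncnorm_parent(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu0, sigma0) of a zero-truncated normal with given moments.

    Solves for a = mu0/sigma0 such that the zero-truncated normal's CV equals
    sd/mean, then scales.  Feasible for CV below 1 (CV -> 1 as a -> -inf;
    CV = sqrt(pi/2 - 1) ~ 0.76 for the half-normal at a = 0).
    """
    cv = sd / mean

    def trunc_moments(a: float) -> tuple[float, float]:
        # hazard of the standard normal at -a: E[Z | Z > -a] = h
        h = stats.norm.pdf(a) / stats.norm.cdf(a)
        m = a + h                      # post-truncation mean in sigma0 units
        v = 1.0 - a * h - h * h        # post-truncation variance factor
        return m, v

    def cv_err(a: float) -> float:
        m, v = trunc_moments(a)
        return np.sqrt(max(v, 0.0)) / m - cv

    a_lo, a_hi = -6.0, max(10.0, 3.0 / cv)
    a = optimize.brentq(cv_err, a_lo, a_hi, xtol=1e-12)
    m, v = trunc_moments(a)
    sigma0 = sd / np.sqrt(v)
    mu0 = a * sigma0
    # rescale so the post-truncation mean lands exactly on `mean`
    scale = mean / (mu0 + sigma0 * (m - a))
    return mu0 * scale, sigma0 * scale


def _naive_mean_shift(cv: float) -> float:
    """Relative mean shift caused by zero-truncating N(mean, (cv*mean)^2)."""
    alpha = -1.0 / cv
    lam = stats.norm.pdf(alpha) / (1.0 - stats.norm.cdf(alpha))
    return cv * lam


def _draw_window(
    rng: np.random.Generator, n: int, mean: float, delta: float
) -> tuple[np.ndarray, str | None]:
    """Draw n i.i.d. samples with target mean and CV = delta; maybe a warning."""
    if delta == 0.0:
        return np.full(n, mean), None
    warning = None
    if _naive_mean_shift(delta) > MEAN_SHIFT_WARN_FRACTION:
        warning = (
            f"target delta {delta:.3f} is large enough that zero-truncation "
            f"shifts the window mean by more than "
            f"{MEAN_SHIFT_WARN_FRACTION:.0%}"
        )
    if delta >= _CV_FEASIBLE_MAX:
        # infeasible for a zero-truncated normal; draw with naive parameters
        mu0, sigma0 = mean, delta * mean
    else:
        mu0, sigma0 = _truncnorm_parent(mean, delta * mean)
    a = (0.0 - mu0) / sigma0
    samples = stats.truncnorm.rvs(
        a, np.inf, loc=mu0, scale=sigma0, size=n, random_state=rng
    )
    return samples, warning


def simulate_session(spec: SimulationSpec) -> SimulationResult:
    """Simulate one full session envelope from a :class:`SimulationSpec`.

    Deterministic for a fixed spec (the seed drives a dedicated generator);
    the returned warnings list any windows whose target delta strains the
    truncated-normal noise model.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    windows = extract_windows(spec.schedule)
    n_total = int(round(spec.schedule.span_s * fs))
    samples = np.zeros(n_total)
    filled = np.zeros(n_total, dtype=bool)
    warnings: list[str] = []

    # windows sorted by time so the seeded draw order is well defined
    def window_mean(w) -> float:
        if hasattr(w, "block_index"):  # self window
            return spec.base_mean[w.state]
        return 0.5 * (spec.base_mean[w.from_state] + spec.base_mean[w.to_state])

    def window_delta(w) -> float:
        if hasattr(w, "block_index"):
            return spec.target_delta[(w.state, w.state)]
        return spec.target_delta[(w.from_state, w.to_state)]

    def window_label(w) -> str:
        if hasattr(w, "block_index"):
            return f"self[{w.state.label}, block {w.block_index}]"
        return f"cross[{w.from_state.label}->{w.to_state.label}]"

    ordered = sorted(windows.all_windows(), key=lambda w: w.start_s)
    spans: list[tuple[int, int, float]] = []  # (i0, i1, mean) for filler ramps
    for w in ordered:
        i0 = int(np.floor(w.start_s * fs + 1e-9))
        i1 = int(np.floor(w.end_s * fs + 1e-9))
        mean, delta = window_mean(w), window_delta(w)
        draw, warning = _draw_window(rng, i1 - i0, mean, delta)
        if warning is not None:
            warnings.append(f"{window_label(w)}: {warning}")
        samples[i0:i1] = draw
        filled[i0:i1] = True
        spans.append((i0, i1, mean))

    # filler: linear ramp between neighbouring window means; flat at the ends
    first_i0, _, first_mean = spans[0]
    samples[:first_i0] = first_mean
    _, last_i1, last_mean = spans[-1]
    samples[last_i1:] = last_mean
    for (_, a_end, a_mean), (b_start, _, b_mean) in zip(spans[:-1], spans[1:]):
        gap = b_start - a_end
        if gap > 0:
            samples[a_end:b_start] = np.linspace(a_mean, b_mean, gap, endpoint=False)

    signal = EnvelopeSignal(
        samples=samples, sampling_rate=fs, t0=0.0, channel_name="simulated_envelope"
    )
    return SimulationResult(signal=signal, windows=windows, warnings=tuple(warnings))


def make_phenotype(flexibility: str, seed: int) -> SimulationSpec:
    """Spec whose target deltas equal the published calibration matrix.

    The published matrices are already row-normalized (up to 2-dp print
    rounding), so using their entries directly as target deltas means the
    pipeline's normalized matrix should recover the published one.
    """
    raw = reference_matrix_raw(flexibility)  # raises on bad label
    schedule = generate_block_sequence(seed)
    delta = {
        (i, j): float(raw[int(i), int(j)]) for i in STATE_ORDER for j in STATE_ORDER
    }
    return SimulationSpec(
        schedule=schedule, target_delta=DeltaIndexSet(delta=delta), seed=seed
    )
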