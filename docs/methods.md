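# Methods

## Model and assumptions

The package treats a session of affective experience as a discrete-time
Markov chain over four states — Stress, Engagement, Boring, Relax, the
quadrants of the valence–arousal circumplex, always in that fixed order. The
chain is not fitted to observed state sequences; its transition weights are
*variability shares* derived from a physiological envelope:

1. **δ index.** For a window of the nonnegative envelope, δ = sample SD /
   |mean| — the coefficient of variation. It is dimensionless and invariant
   under positive rescaling, so recordings with different gains, units, or
   electrode impedances are comparable. The Markov property is adopted by
   design: each window is summarized independently, and a transition's weight
   depends only on the window at that boundary.
2. **Window placement.** The 12 cross-transition windows are 30 s centred on
   the block boundaries (boundary ± 15 s); the 13 self-state windows are the
   middle 30 s of each block (onset + 45 s to onset + 75 s), the portion most
   representative of the sustained state, 45 s clear of both adjacent
   transitions. Windows are half-open, [start, end), and a sample at time t
   maps to index floor((t − t0)·fs), so adjacent windows partition samples
   with no double counting.
3. **Δ matrix.** The 16 δ values (12 cross + 4 self, the self values averaged
   per state across that state's 3–4 blocks) fill a 4×4 array that is
   row-normalized: Δᵢⱼ = δᵢⱼ / Σⱼ δᵢⱼ. Rows sum to 1 by construction, making
   Δ a row-stochastic transition matrix whose entries are shares of each
   row's total variability — high diagonal mass reads as rigidity, high
   off-diagonal mass as flexibility.
4. **Steady state.** The model's operational steady state is the distribution
   after **five** propagation steps from the uniform start (0.25, 0.25, 0.25,
   0.25): S₅ = S₀P⁵. This is a finite-horizon summary, not the asymptotic
   limit; the claim that the starting distribution does not matter is only
   true asymptotically, which is why the uniform start is part of the
   definition and why the exact eigenvector stationary distribution
   (π P = π, solved via the null space of Pᵀ − I after an irreducibility
   check on the embedded digraph) is exposed as a clearly separate
   operation. For the published calibration matrices the two agree to ~0.01.
5. **Source/receiver indices.** Off-diagonal row sums (source: how strongly a
   state emits transitions; source(i) = 1 − Δᵢᵢ) and off-diagonal column sums
   (receiver: how strongly it attracts them).

## Session design

Thirteen 120-s blocks (12 pictures × 10 s each) must realize each of the 12
ordered transitions between distinct states exactly once. The only design
satisfying this is an Eulerian circuit on the complete 4-vertex digraph;
sequences are generated by a randomized Hierholzer traversal, seeded and
bit-reproducible. A consequence of the degree structure (every state has in-
and out-degree 3) is that the start state — which is also the end state —
occupies 4 blocks and each other state 3; the test suite verifies this
against a brute-force enumeration of all Eulerian circuits.

Screening thresholds (CFI and CFS both > 6 → high, both < 3 → low, otherwise
intermediate) are interpreted as mean item scores, since both instruments are
Likert-item questionnaires; the intermediate group is labelled and retained,
never discarded, and every downstream operation accepts any group.

## Tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `smooth_ms` | 100 | ms | Moving-average width after rectification of a raw signed signal; ~100 ms is a conventional EMG-envelope smoother. Ignored when the input is already an envelope. |
| `sd_ddof` | 1 | — | Sample (n−1) SD in δ: the small-sample convention. Configurable to 0; every invariance result holds either way. |
| `steady_steps` | 5 | steps | The operational steady-state horizon, part of the model definition. |
| `row_sum_tol` | 0.02 | — | Tolerated row-sum deviation when reading a matrix CSV; published matrices are printed at 2 dp, so a row can sum to 0.99. Repairs are renormalized and logged, never silent. |
| `screen_high` / `screen_low` | 6 / 3 | score | CFI/CFS group thresholds. |
| sampling rate | 100 (simulator) | Hz | Any rate ≥ ingest is accepted; the protocol does not fix one, and δ is rate-robust (a 30-s window at 100 Hz gives n = 3000, SE of the CV estimate ≈ 0.005 at δ ≈ 0.3). |
| degenerate-mean guard | 1e-12 | signal units | A window mean this close to zero makes δ meaningless; the error names the offending window. A zero-mean situation indicates raw (unrectified) input, which is why envelope preprocessing exists. |

## Synthetic sessions

The simulator emulates the calibration recording: a 1560-s nonnegative
envelope at 100 Hz in which every analysis window carries a prescribed
coefficient of variation. Within a window, samples are i.i.d. zero-truncated
normal with *post-truncation* mean equal to the window's base amplitude and
post-truncation SD equal to δ × mean — the parent parameters are solved by
moment matching (Brent root-solve on the parent mean/SD ratio), so the
realized CV is an unbiased estimator of the target. A zero-truncated normal
cannot exceed CV 1 (and reaches the half-normal's ≈ 0.76 only at zero parent
mean); targets ≥ 0.99 fall back to naive parametrization, and any target
large enough that zero-truncation of a normal with those moments would shift
its mean by more than 10% is recorded as an infeasibility warning in the
simulation result and manifest.

Per-state base amplitudes default to 12 (Stress), 6 (Engagement), 8 (Boring),
4 (Relax) μV — corrugator activity rises with negative valence, so the
negative-valence states sit higher; the exact values are irrelevant to every
derived index because δ is scale-free. Cross windows use the mean of the two
flanking states' base amplitudes. Between analysis windows the signal ramps
linearly from one window's mean to the next; only the analysis windows carry
contract guarantees, so the filler is chosen purely for continuity.

The phenotype generator uses the published high- and low-flexibility
calibration matrices directly as target δ sets (they are already
row-normalized up to print rounding), so an end-to-end run — simulate,
window, δ, normalize — should recover the published matrix. Averaged over 20
seeds, recovery is within 0.05 per entry and 0.03 per steady-state component
(tolerances sized from the CV-estimator standard error at n = 3000); the
measured errors are an order of magnitude smaller.

What the simulator does **not** emulate: EMG spectral content, habituation
or drift across blocks, motion artifacts, inter-subject amplitude
variability, or any autocorrelation within windows (samples are i.i.d., so a
passing recovery test validates the estimator chain, not robustness to
correlated physiological noise).

## Numerical choices

- Row-stochasticity and simplex membership are enforced at 1e-9 on every
  constructed matrix and distribution.
- Propagation uses `numpy.linalg.matrix_power` (binary exponentiation), so
  the 10⁴-step power-iteration oracle used to validate the eigenvector
  stationary distribution is cheap and exact to ~1e-12.
- The stationary solver requires irreducibility (strong connectivity of the
  positive-entry digraph, via networkx) and a one-dimensional null space, and
  verifies ‖πP − π‖∞ < 1e-10 before returning; the identity matrix and other
  reducible chains raise a dedicated error.
- Matrix CSVs are read tolerantly: rows within 0.02 of sum 1 are renormalized
  with a warning (published matrices carry 2-dp rounding), larger deviations
  are rejected. Raw (unnormalized) load and write round-trip bit-exactly.
- Window-to-index mapping adds 1e-9 s of slack before flooring to absorb
  float error in times; the pipeline's signal-covers-schedule check likewise
  tolerates one sample period, since a time column round-tripped through CSV
  can infer a sampling rate a few ULPs off nominal.

## Known inconsistencies in the published calibration

The published five-step steady state of the **low-flexibility** matrix is
reported as (0.26, 0.29, 0.22, 0.22), but propagating the published matrix
itself yields (0.29, 0.23, 0.26, 0.21) — maximum 0.29 on **Stress**, which is
what the accompanying text describes ("highest peak … for the stress block,
0.29"). The package reproduces the self-consistent propagation and the
textual peak; the printed row appears to have been permuted or mislabelled
and is deliberately not targeted. Similarly, the text's aside attributing
0.29 to "the boring block and 0.43 for the stress block" for the
high-flexibility participant conflicts with the table's own column labels;
the table (0.43 on Boring, 0.28 on Stress) is taken as authoritative, and it
is the table that the five-step propagation reproduces exactly.

## Limitations

- Transition weights are variability shares, not empirical transition
  frequencies; interpreting Δ as a behavioural transition probability is a
  modelling stance, supported here only by the two-participant calibration.
- One channel (corrugator f-EMG) proxies one affect dimension (negative
  valence); zygomatic EMG, skin conductance, respiration, and heart-rate
  variability are out of scope.
- Each cross window yields a single δ estimate — there is no replication of
  transitions within a session, so per-entry uncertainty cannot be estimated
  from one recording.
- The five-step steady state inherits dependence on the uniform start; the
  eigenvector stationary distribution should be used for any asymptotic
  claim.
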