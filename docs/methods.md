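# Methods

`patrolfret` analyses single-molecule FRET recordings of a junction-anchored
reeling translocase — a helicase monomer that binds a 3′ ss–dsDNA junction,
reels in the 3′ ssDNA tail one nucleotide at a time while extruding a loop,
releases the loop, and repeats. The same periodic "patrolling" unwinds an
intramolecular G-quadruplex (G4) placed in its path, in three discrete steps,
on every cycle. Because no raw traces are publicly available for this class
of experiment, the package pairs every analysis with a calibrated stochastic
simulator that carries ground truth, so each estimator is validated by
parameter recovery.

## Observables and model

A molecule is observed as two fluorescence channels (donor I_D, acceptor
I_A) at a fixed frame interval (default 30 ms). The apparent FRET efficiency
is

    E = A / (A + D),   D = I_D − bg_D,   A = I_A − bg_A − l·D,

with backgrounds bg and donor→acceptor leakage l (defaults 0; no gamma
correction — E is apparent, which suffices for relative-state analysis).
Frames with non-positive corrected total are masked, not deleted, so frame
indices stay aligned for cycle detection; traces that are dark on more than
half their frames are rejected as bleached/empty.

### Patrolling kinetics

The hidden position n(t) on a track of N nt advances by exponential 1-nt
waits at rate

    r(S) = k_max · S / (K_M + S)

([ATP] = S), and resets at n = N after an optional exponential release dwell.
E is mapped linearly between the two construct anchors — the simplest
monotone map consistent with the gradual sawtooth rise; the data constrain
only the endpoints. A cycle duration is then Γ-distributed:
Δt ~ Γ(shape n_steps, rate r), the basis of hidden-step counting.

Estimators:

* **Cycle detection** — hysteresis state machine: for a rising sawtooth, a
  boundary is the downward crossing of the low threshold after an excursion
  above the high threshold (thresholds default to anchors ± 25% of the anchor
  span). A centered 3-frame running median suppresses shot-noise
  re-crossings; wider windows were measured to bias fast (~20-frame) cycles
  and are not used by default. Boundaries closer than `min_dwell_s` (0.15 s)
  merge. First/last truncated dwells never enter statistics because dwells
  are differences of interior boundaries.
* **Γ hidden-step fit** — profile-likelihood MLE: the shape solves
  log(n) − ψ(n) = log(mean) − mean(log Δt) (Brent root-find), rate k = n/mean.
  This is exactly scale-equivariant. SEs come from the observed information
  matrix; a nonparametric bootstrap and a binned least-squares fit are
  available as cross-checks. The kinetic step size is bounded by N/n; an
  integer step is only reported when the bound is below 2 nt.
* **Speed** — weighted linear regression τ = N/v + b across track lengths;
  v = 1/slope with propagated SE. The saturating speed is
  v_max = v·(K_M + S)/S.
* **ATP coupling** — nonlinear least squares of 1/τ = r_max·S/(K_M + S).

### G4 unwinding cycles

Each cycle is: patrol over the ssDNA track (the dyes flank the G4, so this
phase sits at the folded FRET level), then a descending four-level ladder
folded → I1 → I2 → unfolded whose three stage dwells are sums of
`g4_stage_substeps` (default 4/8/9) exponential 1-nt waits at the patrol
rate, then reeling of the residual unfolded nucleotides (Δt4, the G4 length
minus the substeps already spent, Γ-distributed), loop release, and
exponential refolding (Δt5, default rate 5 s⁻¹ → 0.2 s mean) back to the
folded level.

Two modelling choices deserve note:

* **Δt5 visibility.** The refolding interval is only measurable if the trace
  distinguishes "unfolded, loop held" from "unfolded, loop released". The
  simulator gives the released state its own FRET level (default 0.38,
  between the unfolded 0.30 and intermediate 0.45): releasing the loop lets
  the stretched ssDNA relax slightly. Classification measures Δt5 as the
  time from the unfolded plateau's end to the folded recovery; when the
  short released plateau is not resolved by the step finder Δt5 collapses
  to ~0, and the dwell fits drop those zeros — the reported refolding mean
  is therefore length-biased upward by the 3-frame resolution floor (a
  ~0.2 s dwell at 30-ms frames sits near that floor by construction).
* **Intermediate levels.** The two intermediate FRET values (0.60, 0.45) are
  plausible placeholders between the measured folded/unfolded anchors; the
  source experiments show them only graphically.

### Step finding

Kerssemakers-style greedy chi-square placement: at each round, insert the
single step (location plus two plateau means) that maximally reduces the
SSE, computed in O(n) from prefix sums. The step count is selected by a
change-point BIC, n·log(SSE/n) + (2k+2)·log n, along the nested greedy path.
The classical counter-fit quality ratio (steps forced to mid-plateau
positions; SSE_counter/SSE_fit) is computed for the selected fit and used
only as a goodness floor: in testing it peaks at one step on multi-step
ladders (the largest FRET drop dominates it) and therefore cannot select
the count. Plateaus shorter than 3 frames are never created — sub-resolution
dwells are not believable and unconstrained one-frame segments let any
segmenter chase outliers. An exhaustive dynamic-programming segmentation
(globally optimal SSE at each step count, same selection rule) serves as the
oracle in tests; greedy/DP step-count agreement exceeds 95% on small
high-SNR instances.

Cycle classification requires exactly three downward steps as the first
three transitions (folded → I1 → I2 → unfolded); other cycles are flagged
non-canonical and counted but excluded from dwell statistics, so the
"three-step unwinding" claim is testable as a modal statement. Pooled
plateau levels are decomposed with a BIC-selected Gaussian mixture
(`sklearn`); four components is the three-intermediate-step signature.

### Ensemble kinetics

Spot-count survival: each tethered molecule carries an exponential (or
two-phase mixture) unwinding time; counts at the observation times are the
survivors, hence binomial with survival e^(−t/t_unwind) and monotone per
realisation. Fitting uses plain least squares on normalized counts; `auto`
model selection accepts the bi-exponential only when it wins by >4 corrected
AIC units with both phases ≥5% weight (guards against noise-driven second
phases). Cycles-per-unwinding divides t_unwind by the patrol period and also
reports the value rounded to one significant figure ("about 200").

Binding titrations: per-molecule initial-window (0.15 s = 5 frames) mean E
values are histogrammed (bins 0.025 wide over [−0.1, 1.1]); the bound
fraction is the low-E weight of a two-Gaussian weighted least-squares fit
(BIC fallback to one component, and components closer than their widths are
collapsed — an unresolved pair is one population). K_D comes from
f = c/(c + K_D).

## Simulator defaults (the stated world)

| parameter | default | origin |
|---|---|---|
| frame interval | 30 ms | recording resolution |
| k_step_max | 85 s⁻¹ | saturating speed 85 nt/s at 1-nt steps |
| K_M (ATP) | 110 μM | patrol-rate titration |
| K_D | 7 nM | binding titration half-occupancy |
| t_unwind | 6.3 min | heteroduplex survival at 20 μM ATP |
| refold rate | 5 s⁻¹ | ~0.2 s refolding dwell |
| G4 substeps | 4/8/9 | plausible split of the 31-nt motif; configurable |
| anchors (mid-labeled) | 0.37 / 0.58 | measured bound/free populations |
| anchors (end-labeled) | 0.30 / 0.80 | chosen full-amplitude sawtooth (not printed) |
| G4 anchors | 0.30 / 0.75 | measured unfolded/folded levels |
| noise | Gaussian, SNR 5 | σ_c = I_c/SNR per channel, floor 5% of budget |

Noise model rationale: an additive σ = total/SNR split across channels gives
per-frame FRET noise ≈ 0.11, well above what 30-ms smFRET recordings show
and enough to defeat any step finder on 0.15-spaced levels; the
multiplicative per-channel form gives σ_E ≈ 0.05–0.07 at SNR 5, which
matches both typical recordings and the ~0.05 population widths the
analysis assumes. Optional photon-exact Poisson noise and noise-free output
are provided; donor/acceptor bleaching and a donor PIFE gain are available
but off by default.

Randomness: every simulation takes an explicit integer seed; a master seed
spawns per-molecule streams through `numpy` SeedSequence, so molecule i is
reproducible in isolation and identical seed + parameters give bit-identical
output.

## What the simulator does not emulate

Real recordings contain drift, blinking, multi-molecule colocalisation,
heterogeneous per-molecule speeds (the analysis handles these — pooling
heterogeneous molecules demonstrably lowers the apparent hidden-step count —
but the generator draws one rate per parameter set), PIFE photophysics
beyond a constant gain, and drug-dependent quenching. A green recovery test
therefore establishes that the estimator is correct for the stated kinetic
model at realistic noise, not that it is robust to every instrumental
artifact.

## Numerical choices

* Γ MLE bracketing: shape solved on [1e-6, max(4, 2/s)] with doubling; the
  degenerate all-equal-dwells case returns infinite shape rather than
  failing.
* Mixture fits run `n_init=3` with a fixed random state; BIC across 1..6
  components.
* Michaelis–Menten fitted unweighted by default (inverse-variance weights
  optional when τ SEs are supplied), start at 1.5·max(rate), median(S).
* Exponential survival fits start at half the observation span; bi-exponential
  at (span/10, span).
* Trace tables are written at %.17g so the write→read round trip is
  bit-exact (`float_precision="round_trip"` on read).
* detect_cycles returns a diagnostic, not an error, when fewer than two
  boundaries exist; irregular traces (no clean sawtooth) simply yield few or
  no dwells.

## Known limitations

* Dwells shorter than ~3 frames (90 ms) are unresolvable by design; at
  500 μM ATP the ~0.5 s patrol period loses a few percent of cycles, which
  biases the fitted K_M slightly downward in full-chain recovery (within the
  tested 15%).
* The refolding-time estimate is biased by the resolution floor (see above).
* Hidden-step counting on detected (rather than true) boundaries inflates
  dwell variance by boundary jitter, lowering the apparent shape n; the
  effect is small when the period is ≳30 frames, which is why the
  single-molecule design uses a ~1 s period.
* No hidden-Markov step inference within a cycle: individual 1-nt steps are
  far below the noise floor, and only stage-level dwells are analysed.
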