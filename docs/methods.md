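# Methods

## Outcome definition

The target is per-visit cognitive conversion.  With ADAS-cog score
`A(t)` (0–70, higher = worse) at months t ∈ {0, 3, 6}:

    CI at t  ⇔  A(0) − A(t) ≥ 4        (t = 3, 6)

and CNI otherwise.  Both follow-up labels are referenced to baseline: in
the cohort the analysis emulates, the 3- and 6-month CI counts (85 and 84
of 224) are parallel baseline-referenced quantities, not chained
increments.  The reference month is configurable.  A label is defined
only when both the baseline and the follow-up score are observed;
undefined pairs are omitted and reported, never imputed.

## Synthetic cohort generator

The study cohorts are private, so every stage runs against a generator
that emulates their structure.  What it reproduces:

- **Static marginals** — age N(69.75, 8.52²) clipped to [50, 89] (so the
  reporting age bands partition the cohort), education, height, weight,
  HIS as clipped normals; eight comorbidities as independent Bernoulli at
  the published prevalences; gender Bernoulli with p(female) = 137/224
  (the demographics table's itemized rows, which conflict with the prose;
  the table was followed); family history 45/224; intervention arm
  categorical at 62/22/55/38/47 of 224.
- **ADAS-cog trajectories** — `A(t) = A(0) + (t/3)·δ_arm + e_t` with
  stationary AR(1) noise across visits: `e_3 = σ z₁`,
  `e_6 = ρ e_3 + σ√(1−ρ²) z₂`; defaults σ = 3 points, ρ = 0.5.  The
  autocorrelation makes the 3-month visit informative for the 6-month
  outcome, which is exactly the property the withdrawal experiment
  measures; ρ = 0 would make withdrawal free, ρ → 1 maximally costly.
- **Arm drifts** (points per 3-month step; negative = improvement):
  observation −0.8, exercise −2.6, donepezil −3.7, GBE −4.6, combination
  −3.8.  These were chosen once by probit matching: with
  P(CI) = Φ((−4 − δ)/σ) at σ = 3, they land on the published per-arm
  3-month conversion fractions (9/62, 7/22, 25/55, 22/38, 22/47).
- **Secondary scales** — each scale X is
  `X(t) = X(0) + c·(σ_X/σ_A)·dir_X·ΔA(t) + 0.3σ_X ε`, where dir_X encodes
  clinical direction (MMSE, IADL, QOL-AD, DSST improve when ADAS-cog
  falls; NPI, GDS, anxiety, CDR, TMT-A/B worsen with it) and the coupling
  c defaults to 0.5.  The true joint distribution of the scales is not
  published; c is a tunable, not an estimate.
- **Diagnosis class** — baseline MMSE ≥ 24 → MCI, else AD (threshold
  configurable).

Known departures from the real data: the linear-in-time drift implies
6-month conversion prevalence well above the study's roughly constant
~38% (the real treatment effect evidently plateaus after the first
interval); there is no dropout/attrition; comorbidities are independent;
no biomarkers exist in either the real or synthetic schema.  Passing
tests therefore demonstrate correctness of the machinery and recovery of
planted signals — not real-data performance, which is out of reach
without the private cohorts.

Scale values are clipped to their instrument ranges post-generation;
clip counts are logged on the returned table.  Missingness is injected
independently per cell at configurable per-feature rates; baseline
ADAS-cog is never removed so labels stay definable.

## Preprocessing

The 50%-missing exclusion rule is ambiguous between a per-patient and a
per-feature reading; both are applied — features observed in <50% of
patients are dropped first, then patients with >50% of the remaining
cells missing are excluded (both thresholds configurable).  Imputation is
column mean for continuous features (per visit month for time-dependent
ones) and mode for binary/categorical, with mode ties broken to the
sorted-first value for determinism.  Standardization uses the population
(n-denominator) standard deviation so the fit set has exactly unit
variance; zero-variance features map to 0 and are flagged.  By default
scalers are fit on training folds only; the original analysis normalized
the whole dataset before cross-validation, and `pooled_scaling`
restores that behavior when fidelity matters more than leakage hygiene.

## Model

- Static encoder: exactly five fully connected ReLU layers (default
  widths 64-64-32-32-16; the source architecture's widths are not
  published) and a logistic head → scalar score s.
- Recurrent core: single-layer LSTM, hidden size 32, unrolled over the
  input visits (months 0 and 3).  Step input = that visit's eleven scale
  values ++ s ++ previous-step outcome.  The static score is concatenated
  at every step — the minimal reading of a single score "fusing" into the
  sequence model.
- Attention: scaled dot-product over the hidden states produced so far
  (query = current hidden state, keys = values = hidden states; no
  learned projections, d = hidden size).  The attended context feeds a
  shared logistic head: step 1 → P(CI at 3 months), step 2 → P(CI at 6
  months).
- Teacher forcing: the true 3-month label enters the step-2 input during
  training; at inference the model's own thresholded prediction (≥ 0.5)
  is fed back (feeding the probability instead is available via
  `teacher_signal="probability"`).  With a single step the toggle is a
  no-op by construction.
- Training: full-batch Adam (the configured batch size, 3600, exceeds
  any realistic fold), summed per-step binary cross-entropy in the
  numerically stable logit form, learning rate 0.01 multiplied by 0.1 at
  epochs 400 and 800, 1000 epochs.  The delivered model is the epoch with
  the highest 6-month AUC on a stratified 20% validation split of the
  training fold (the selection horizon is a package choice; the source
  criterion does not specify one).  Single-class labels at any step are
  an error since AUC-based selection is undefined.
- Implementation: a ~200-line reverse-mode autodiff tape over numpy
  (`cogconv.nn`), gradient-checked against central finite differences in
  the test suite.  Everything is float64 and seed-deterministic;
  identical config + seed reproduces weights bit-for-bit.

## Evaluation

Stratified five-fold cross-validation (stratified by the 6-month label;
fold sizes differ by ≤ 1).  Per fold and horizon the cutoff is the
Youden-optimal threshold over midpoints of the fold's unique held-out
scores plus ±∞, ties resolved to the lowest threshold (favoring
sensitivity); a degenerate ±∞ optimum is mapped to the equivalent finite
all-positive/all-negative cutoff.  Proportion CIs are exact
Clopper–Pearson; AUC CIs use DeLong's variance (the source's CI method is
unstated; this is configurable in principle via direct calls); AUPRC is
the step-wise non-interpolated precision–recall summation (average
precision); pooled AUC across folds is mean ± z·sd/√k with ddof = 1, the
convention under which the published per-fold values reproduce the
published pooled intervals to rounding.  The positive class is CI,
consistent with the published per-fold prevalence (~16 of 45).

**Withdrawal experiment.**  Trained fold models are re-scored — never
retrained — on their held-out patients with the 3-month step removed, so
each withdrawn input sequence has length 1 and its single output is used
as the 6-month prediction (a zero-fill mode that keeps the step but
blanks its features exists for comparison).  This reading is consistent
with the published withdrawn 6-month AUC essentially matching the
3-month AUC.  Reported per fold: full AUC, withdrawn AUC, difference.

## Decision analysis

Flag = CNI at the follow-up in question (this per-time-point reading
reproduces the published 139/224 and 140/224 exactly; a cumulative
"CNI at any follow-up so far" reading is available).  Actual and
predicted flag rates are compared with the uncorrected Pearson chi-square
on the 2×2 table; whenever any expected cell count is below 5 the test
routes to Fisher's two-sided exact test (matching the dash-marked
statistic cells in the published stratified table; a Yates-corrected mode
exists since the adjustment used there is not named).  Because actual and
predicted flags describe the same patients, the unpaired test is
statistically questionable; it is kept as the faithful default and
McNemar's paired test is provided under an explicit label.  Percentages
print to 2 decimals and statistics to 3, matching the published layout.
Model-predicted labels for this analysis are the out-of-fold predictions
at each fold's Youden cutoff, so every patient is scored by a model that
never saw them.

## Problem sizes and benchmarks

The planted-signal benchmark uses a two-arm cohort (n = 600, drift
separation 4 points per step, σ = 2, ρ = 0.5, full 1000-epoch schedule,
five folds); a logistic-regression oracle on the same design confirms the
signal is linearly recoverable (AUC ≈ 0.99 in-sample), and the hybrid
model's held-out 6-month AUC clears 0.85 with a wide margin (~0.95).  The
withdrawal study uses ten independent replicates at n = 400 with a
300-epoch schedule — the ordering (full ≥ withdrawn on average) is stable
across seeds and does not require the full schedule.  The end-to-end
pipeline demo and tests use reduced epochs and cohort sizes chosen to
keep runs short while preserving every structural property being
checked.

## Limitations

- Real-data headline numbers (pooled AUCs 0.735/0.853, accuracies
  70.09%/81.70%) are not reproducible without the private cohorts; the
  package's claims about the model are structural and
  synthetic-benchmark-based.
- The generator's linear drift overshoots 6-month conversion prevalence
  (see above); per-arm 6-month margins should not be read as calibrated.
- Some sub-rows of the published stratified reassignment table have
  internally inconsistent denominators; they are not reproduced as
  targets.
- The unpaired chi-square on paired flags inflates apparent evidence;
  use `mcnemar_test` for inference you intend to act on.
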