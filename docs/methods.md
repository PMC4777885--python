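# Methods

## Data model and units

Daily measurements are calendar-day granular (one value per day per
modality). Weight is kept in kilograms; transthoracic bio-impedance is
log-transformed on load (natural log — raw impedance in the tens of ohms is
right-skewed, and the natural-log scale puts typical values near 3.4
log-ohm). Base-10 is available via `load_cohort(..., log_base="10")`. The
loader accepts already-transformed data tagged `nitti_log_ohm` and never
transforms twice. Rules published in pounds are converted at 0.45 kg/lb.

Each patient carries a monitoring interval; hospitalizations split it into
*blocks*, with a 7-day post-admission pause (the hospital stay) before
monitoring resumes. All algorithm state — moving-average windows and the
CUSUM sum — is reset at every block start, so pre-admission data never leaks
across a hospitalization.

## Imputation and causality

Interior gaps are linearly interpolated onto the daily grid; leading and
trailing days outside the observation span are never filled. This emulates a
real-time system that retro-fills a gap when the closing observation
arrives. To keep every reported value real-time computable, index entries
are emitted **on observed days only**: imputed days contribute to trailing
windows but carry no index value of their own (an index value on an imputed
day would depend on an observation arriving after that day). Consequence,
verified by test: every index value at day t is invariant to deleting all
data after t.

Adherence is counted on observed values only. The default rule requires ≥ 3
observed measurements in *each* 7-day half of a 14-day window (the stricter
reading of a 3-per-week minimum); a lenient mode (≥ 6 per fortnight) is
selectable.

## Output indices

- **RoT**: x_t − x_{t−d}, lag d ∈ [1, 21] days. Warmup d days.
- **MACD**: trailing simple moving averages, SMA_{N_s} − SMA_{N_l},
  1 ≤ N_s < N_l. Warmup N_l − 1 days. (Exponential averages are a
  conceivable variant; the simple form is used throughout.)
- **CUSUM**: z-scores against the trailing d-day mean and sample SD
  (current day excluded, so a fresh deviation is scored against its
  pre-deviation baseline), one-sided accumulation beyond allowance c,
  clamped at zero. σ is floored at 10⁻⁶ measurement units to survive
  locally constant windows. An alternative "depreciation" reading —
  multiplicative decay of the sum — is not implemented; the clamp-plus-
  allowance form matches the standard control-chart formulation.

Directions are tied to physiology: weight alerts on increase, NITTI on
decrease. CUSUM is translation- and scale-invariant (standardization);
RoT/MACD are translation-invariant and scale-equivariant.

## Period labeling

Monitoring blocks are tiled into 14-day end-inclusive windows; a block
ending in a decompensation is tiled backward from the admission day, other
blocks forward, partial leftovers discarded. A window is evaluated only if
(a) it meets the adherence rule, (b) the algorithm's warmup is complete
before the window starts — a long-memory detector given no pre-window
baseline cannot be scored fairly, and such events are excluded from the
analysis rather than counted as misses — and (c) at least one index value
falls inside it. Each window is scored by its *peak* index (most extreme in
the alert direction), which is equivalent to "any alert day in the window"
for every monotone threshold.

Non-HF hospitalizations end no evaluation period and create no event label,
but the post-admission monitoring pause still applies.

## ROC, partial AUC, thresholds

The ROC sweeps all distinct peak values; reported thresholds are midpoints
between consecutive distinct scores so that the strict firing rule
(index beyond threshold) reproduces each swept operating point exactly —
important when noise-free data produce tied peaks. Partial AUC integrates
the staircase by trapezoid over specificity ∈ [s_min, 1] and is normalized
by (1 − s_min); normalization does not affect the argmax used in parameter
selection. The operating threshold is the Youden point (max sens + spec − 1)
among points with specificity strictly above the floor (default 0.90), ties
broken toward higher specificity.

## Cross-validation

Eight folds, stratified: event patients are dealt round-robin (shuffled,
heaviest event counts first — exact event balance is impossible when
patients have 2+ events), then event-free patients fill folds smallest-
first; patient counts differ by ≤ 1. Per fold, the parameter grid is scored
on the training folds by normalized partial AUC (specificity > 0.95), ties
toward smaller windows. Out-of-fold indices are divided by the magnitude of
the fold's training Youden threshold, so folds with different chosen
parameters pool onto one axis on which 1 marks each fold's own alert
boundary. Threshold-relative scaling is used instead of a raw-index robust
scale because the clamped CUSUM output is zero-inflated: its median absolute
deviation swings by an order of magnitude with the chosen (d, c), which
would place out-of-fold peaks from different folds on incompatible axes. A
MAD × 1.4826 scale (`robust_scale`, with SD and max-|x| fallbacks for
degenerate noise-free indices) is kept as the fallback when the training
threshold is zero or non-finite. The pooled out-of-fold periods form the
unbiased ROC from which the single operating threshold is chosen. Default grids follow the documented ranges (RoT d 1–21; MACD
N_l 10–50 step 5 × N_s 1–10; CUSUM d 10–30 step 5 × c 0.5–1.5 step 0.2) and
are fully configurable; `fast_parameter_grid` provides a small screening
subset spanning the same ranges for simulation studies.

False alarms per patient-year: strictly consecutive above-threshold days
merge into one episode; an episode is false iff no HF admission follows its
onset within 14 days (mirroring the true-positive window); the denominator
is total monitored time. A single 5-week alert therefore counts once here
but up to three times as windowed false positives.

## Mixed-model period comparison

Period means are compared between pre-event and other windows with a linear
mixed model (fixed label effect, random patient intercepts, REML via
statsmodels). A singular or non-finite fit falls back to a permutation test
on the mean difference with a warning. Calibration (uniform p under label
permutation) and recovery of an injected −0.4 log-ohm shift are exercised
in the test suite.

## Synthetic generator

Per patient: monitoring length ~ N(300, 60²) days (floor 28), baselines
weight ~ N(84, 19²) kg and log-NITTI ~ N(3.4, 0.3²) log-ohm, i.i.d. daily
noise (SD 0.6 kg / 0.06 log-ohm), per-day per-modality Bernoulli(0.8)
adherence, and a per-day event hazard of 8.8 × 10⁻⁴ (≈ 24 events per 91
patients over 300 days). Before each event, linear ramps add +2.5 kg and
−0.4 log-ohm over 14 days, reaching the full excursion on the admission
day; measurements pause for 7 days after admission and resume at baseline.
An optional burst-missingness mode (runs of consecutive skipped days)
reproduces realistic adherence-exclusion rates.

What this emulates — and what it does not: real pre-event trajectories are
heterogeneous in shape, onset and size; measurement error is neither
Gaussian nor i.i.d. (wear position, scale surface, family members);
clinicians may intervene and abort decompensations. The generator's clean
linear prodromes make all detectors more accurate than they would be on
real data, and note that a linear ramp to −0.4 log-ohm yields a *window
mean* shift of about −0.2 log-ohm. Passing tests therefore demonstrate the
correctness and internal consistency of the evaluation machinery and the
*relative* behavior of the algorithms, not clinical performance levels.

## Problem sizes in the test suite

Oracle and invariance checks use hundreds of random series of length ≈ 100;
cohort-level checks use the 91-patient default generator (ordering studies
across 20 seeds with the full default grids) or a 32-patient noise-free
cohort for the separable-limit check; the mixed-model calibration uses 200
permutations at 30 patients × 8 periods. These sizes give stable Monte-Carlo
margins while keeping the full suite fast on a single core.

## Known limitations

- Single-modality detectors only; no fusion of weight and NITTI.
- No outlier rejection or plausibility checks on raw measurements.
- Thresholds are global, not per-patient adaptive.
- The false-alarm episode definition (strict day-adjacency, 14-day grace)
  is one reasonable operationalization among several.
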