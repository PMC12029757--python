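# Methods

This note records the models behind `breathgate`, the parameters that
matter, and what the synthetic data can and cannot show.

## Flow segmentation

A sampled expiratory flow trace Q(t) (L/min, uniform grid) is integrated
trapezoidally — the natural reading of a piecewise-linear flow meter — with
a single unit-conversion point (1 L/min = 1000/60 mL/s). The separation
rule is exact arithmetic on the cumulative volume V(t):

1. V₂ = 0.3 · V_total (the anatomical dead space is ~30% of a full
   exhalation; for the textbook 500 mL breath this is 150 mL);
2. t₁ = min{t : V(t) ≥ V₂};
3. t₂ = min{t : V(t) ≥ V(t₁) + V₃}, V₃ being the gas-container volume;
4. the threshold is Q(t₂).

Crossing times are linearly interpolated inside the bracketing sample
interval rather than snapped to the grid: interpolation is consistent with
trapezoidal integration and removes the sample-rate bias (halving the
sampling step moves t₁/t₂ by less than one coarse sample; this is tested).
The threshold is read from the raw, unfiltered trace — flow from a
turbine/differential meter is already smooth at the 100 Hz default, and
filtering would couple the threshold to a filter parameter. Each breath's
own volume feeds the 30% rule, so the pre-experiment adapts to lung
capacity; the three per-breath thresholds are averaged arithmetically.

Parameters: container volume V₃ defaults to 100 mL (a plausible small
enrichment container; it is not fixed by the design and is recorded in
every segmentation result), sampling rate defaults to 100 Hz (flow-meter
class instruments report at tens of Hz; configurable).

Degenerate inputs are explicit errors, not defaults: a zero-volume trace
raises `InsufficientExhalationError`; a breath too small to push the
dead-space front through the container raises `ContainerUnreachableError`.

## Acquisition state machine

The run passes through CLEANING → DEAD_SPACE_REMOVAL → COLLECTION →
DETECTION, each state entered at most once. The collection trigger is
**armed**: the flow must first rise above the threshold before the
below-threshold comparison can fire. The bare rule would trigger at t = 0,
where flow starts at zero; arming is the minimal repair and is the reason a
threshold above peak flow is a hard `NoTriggerError` rather than a silent
whole-breath collection. CLEANING is logged with zero duration at t = 0 —
the trace's time axis is the exhalation itself, and pump/PWM activity is
state metadata with no motor model.

Contamination accounting labels exhaled volume by cumulative rank: the
first 30% of the total is dead-space gas. The stored gas's dead fraction is
then max(0, V₂ − V(t_trigger)) / (V_total − V(t_trigger)); collecting the
whole breath gives 0.30 exactly, and triggering at the trace's own
threshold with V₃ = 0 gives ~0 (≤ 0.02, the residue of interpolating the
flow crossing rather than the volume crossing). Collection is never capped
at V₃ — the container compresses the gas — but the compression ratio is
logged.

## Synthetic cohort

The generator emulates the *statistical structure* of a three-class breath
study, not any particular chemistry.

* **Labels.** Six scale items (0–10) are drawn so the total lands in the
  band of the target class; totals map to poor (≤ 45), good (46–55),
  excellent (≥ 56). A total of exactly 45 sits between the published bands
  and is assigned to poor.
* **Concentrations.** Seven gases with alveolar baselines of order
  0.01–15 ppm are log-normal with within-class log-SD σ = 0.4 per gas.
  Class log-means are displaced along two fixed, near-orthogonal unit
  patterns — poor health elevates the reducing gut/oxidative markers (H₂,
  H₂S, CO, propane), excellent health runs low on the metabolic VOCs
  (acetone, ethanol) — scaled by `effect_size`·σ. The default
  `effect_size = 4` (adjacent-class Mahalanobis distance 4σ, i.e. roughly a
  2–5-fold shift of individual markers against a 1.5-fold within-class
  spread) encodes a clearly separable three-group design: the separability
  a study must have for any classifier to reach the >90% regime the
  pipeline is meant to demonstrate.
* **Dilution.** The analyzed aliquot is c = (1−f)·c_alv + f·c_amb with
  fixed near-ambient levels c_amb (≈ 0 for the endogenous markers;
  atmospheric methane ~2 ppm). The realized f of each subject is jittered
  around the nominal value with sd 0.6·f·(1−f), truncated to [0, 1]: without
  flow-gated valve timing the stored dead-space share tracks breath volume
  and maneuver, so contamination varies strongly around its mean (f = 0 and
  f = 1 stay exact). This variability — not the mean dilution, which in log
  space is mostly a harmless translation — is what degrades classification,
  and it is exactly what per-subject threshold gating removes. The jitter
  uses an RNG stream independent of the concentration draws, so cohorts at
  different f but equal seed are sample-for-sample paired.
* **Sensors.** Ten channels with a fixed, deliberately cross-sensitive
  10×7 sensitivity matrix. Steady state: ratio = 1 + Σⱼ sᵢⱼ cⱼ^α with
  α = 0.5 (typical saturating MOS law). Transient: a fast first-order rise
  (τ = 3.5–6.5 s per channel, weight 0.7) plus a slow component (τ = 40 s,
  weight 0.3) — the two-time-constant behavior of real MOS sensors, which
  keeps the response creeping upward through the 40 s exposure so the
  response maximum sits reproducibly at the exposure end — then first-order
  recovery (τ = 7–13 s) over 20 s, sampled at 5 Hz, with 1% multiplicative
  noise (the t = 0 clean-air sample is exactly 1).

What this does **not** model: adsorption chemistry, temperature/humidity
drift (the hardware handles those by preheating and purging), sensor aging,
real ppm calibration, inter-gas reaction, or any correlation between scale
answers and concentrations beyond the class label. Passing tests therefore
show that the *pipeline* behaves correctly under the assumed statistical
structure, not that a physical device would reach these numbers.

## Features

Each channel is mean-filtered (centered window, default 5 samples, edges
shrink symmetrically) and summarized by five numbers over the full
detection record:

1. integration ratio — ∫(ratio−1)dt / duration. The name denotes the
   time-normalized response area; normalization makes it invariant to the
   record length.
2. maximum location — argmax time as a fraction of the record (0–1);
3. maximum first derivative — max forward difference per second;
4–5. magnitudes of the first two non-DC DFT coefficients of the
   mean-removed curve, a coarse spectral shape summary.

The integration ratio and the spectral pair are definitional
interpretations (several reasonable variants exist); both are deliberately
simple, documented, and swappable. Features are sensor-major
(s01_intratio … s10_f2, 50 values).

## Classification stack

* **LDA.** S_w and S_b from their definitions; solve S_b ω = λ S_w ω via a
  symmetric generalized eigensolver; keep the two leading eigenvectors
  (three classes span at most two discriminant directions), unit-normalized
  with the dominant component positive. S_w is regularized as
  S_w + ε I with ε = shrinkage · tr(S_w)/d. The default shrinkage is 1e-2:
  the five per-channel features are strongly collinear (four of them scale
  with the same steady-state excess) and per-fold sample counts (~92) sit
  near the dimension (50), so a vanishing ridge lets sampling noise steer
  the discriminant directions — 1e-2 matches the magnitude a Ledoit–Wolf
  estimate selects on these tables. Tests that check the eigensolver
  against a closed-form 2×2 oracle pass the shrinkage explicitly.
* **Pipeline scaling.** The projected 2-D scores are z-scored (fitted on
  the training fold) before any kernel classifier: unit-norm directions
  leave the score scale tied to raw feature units, which a fixed-range RBF
  γ cannot absorb.
* **SVM.** One soft-margin RBF machine per class pair (3 for 3 classes),
  each solved by the SMO dual optimizer with tolerance 1e-8; prediction by
  majority vote, vote ties broken by summed signed decision values.
* **GA.** (log₁₀ c, log₁₀ γ) genes over c, γ ∈ [10⁻², 10²]; tournament
  selection (size 3), arithmetic blend crossover (p = 0.8), Gaussian
  log-scale mutation (p = 0.1, sd 0.3 decades), elitism 1 (so the best
  fitness history is non-decreasing), fitness = stratified 5-fold CV
  accuracy, memoized. Defaults: population 20, 50 generations; the bundled
  experiment runner, the acceptance script and the test suite run 10–15
  generations, which on these problem sizes is already past the fitness
  plateau (elitism makes the result a lower bound on longer runs).
* **KNN** (k = 5 default): Euclidean distances, distance ties broken by
  training order, vote ties by smallest mean distance. **RF**: 100 seeded
  bootstrap trees, majority vote. **PCA baseline**: 3 leading components
  of the centered data.
* **Cross-validation.** Stratified 5-fold with a recorded seed; the LDA
  reduction and the classifier are both fitted inside each training fold
  (fitting the projection on the full data would leak test information
  into the 2-D representation). Metrics: overall accuracy, per-class
  recall/precision/F1 from the confusion matrix, zero denominators
  reported as 0.

Hyperparameter selection and the reported CV accuracy share the same folds
(the GA's fitness is the CV accuracy being reported) — the usual protocol
in small-cohort e-nose studies, and the synthetic analogue of comparing
tuned vs untuned settings on one dataset. A nested outer loop would give a
less optimistic estimate; with the default cohort the gap between tuned
and untuned settings here is a few points.

## Problem sizes and numerical choices

Defaults were chosen so every bundled computation runs in seconds on one
CPU: 115 subjects, 301-sample detection records, 5-fold CV, GA populations
of 16–20 with 10–15 generations, grid baselines of 9×9–13×13 points.
Crossing-time interpolation, the ε-ridge, the SVM tolerance (1e-8) and the
tie-break orders above are the only numerical knobs; all are tested at
their defaults.

## Known limitations

* The sensor law and sensitivity matrix are stand-ins with the right
  qualitative shape, not measurements of any hardware.
* The contamination mechanism rests on dilution *variability*; if a real
  device produced perfectly constant contamination, its cost would be the
  (much smaller) power-law compression and noise-floor loss only.
* Accuracy figures are properties of the synthetic design (effect size,
  noise, cohort size) and transfer to real cohorts only insofar as those
  match.
* The GA is a simple real-coded implementation adequate for a smooth 2-D
  landscape; it is not a general-purpose optimizer.
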