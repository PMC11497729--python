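# Methods

## Overview

`amyloidcast` studies how well a single CSF analyte can stand in for a
continuous amyloid-PET measurement. Three pieces interact: a forecaster that
maps one analyte value to 37 regional PET SUVR values, an error-profiling
layer that localizes forecast error along the amyloid axis, and an
asymptotic-regression layer that quantifies where each analyte's forecasts
stop tracking pathology. A synthetic cohort generator supplies data with the
statistical structure the analysis assumes, so every stage is testable end to
end without access to participant data.

## Scales and summary measures

All conversions between SUVR (tracer uptake relative to cerebellar cortex)
and Centiloids use an affine map. The default is the exact fit through the
published anchor pairs (1.42 SUVR, 16.4 CL) and (2.60 SUVR, 69.5 CL), giving
`CL = 45.0·SUVR − 47.5`; any user-supplied map may replace it, and the
underlying tracer-specific calibration is out of scope. Mean cortical burden
is the unweighted arithmetic mean over seven bilateral summary regions
(precuneus, superior frontal, rostral middle frontal, lateral and medial
orbitofrontal, superior and middle temporal). Amyloid positivity is strictly
`mean cortical SUVR > 1.42`; by affine equivalence the same rule in
Centiloids is `> 16.4`.

Cohorts are split 80/20 into train/test; the train count is
`round(0.8·n)` with ties resolved toward training (346 → 277/69).
Stratified splitting (by positivity) is available but off by default.

## The forecaster

Architecture: input (1) → three ReLU hidden layers → linear output (one unit
per region). Exactly three hidden layers; widths, dropout and learning rate
are hyperparameters. Training minimizes mean squared error with mini-batch
ADAM (β₁ = 0.9, β₂ = 0.999, ε = 1e−8, batch 32) for exactly 100 epochs — no
early stopping. Inverted dropout after each hidden activation is active only
during training, so inference needs no rescaling and is deterministic.
Weights are He-scaled normal draws from the config seed; biases start at
zero. The analyte is z-scored with training-set statistics stored on the
model (occupancies ~20% and ratios ~0.05 otherwise need different learning
rates); outputs stay in raw SUVR.

Hyperparameters come from a coarse grid search on an inner 80/20 split of
the training data: widths ∈ {(32,32,16), (64,64,32), (128,64,32)},
dropout ∈ {0.1, 0.3}, learning rate ∈ {1e−3, 1e−2}; selection is minimum
validation MSE with ties broken toward fewer parameters, then lower dropout.
Bootstrap ensembles (default 100 members) retrain on with-replacement
resamples of `round(0.8·|train|)` participants — 64% of the full cohort —
optionally re-tuning each member over a reduced grid; member predictions
feed percentile intervals.

The forward pass is verified in the test suite against a hand-rolled matrix
composition, and 100-epoch training on noiseless linear data must reach the
least-squares solution to MSE < 1e−3.

## Error evaluation

MAPE is always computed on the SUVR scale: Centiloids cross zero, making
relative error undefined, while SUVR stays well above zero. The sliding
window is 25 Centiloids wide, steps 1 CL, and slides along the *predicted*
burden axis by default (observed is available as an option); windows are
half-open `[c − w/2, c + w/2)` and windows with fewer than 10 participants
are reported empty. Within each window, participants are resampled with
replacement 1000 times and the 2.5/97.5 percentiles of the resampled window
MAPE form the 95% band. Two profiles on a shared grid are compared window by
window; analyte A is significantly better where its upper band lies below
B's lower band (non-overlapping 95% CIs — conservative, since no formal test
is defined for this contrast). Contiguous significant windows are merged
into ranges, and the reported crossover is the last center of the first
significant run — the burden level up to which one analyte demonstrably
outperformed the other. Spearman correlations use average ranks and
percentile bootstrap CIs over participants.

## Predictive ceiling

The classical 3-parameter asymptotic regression
`predicted = a + (b − a)·exp(−c·observed)` is fitted by Levenberg–Marquardt
least squares, with predicted mean cortical SUVR as the response and observed
mean cortical SUVR as the regressor (the forecast is the quantity whose upper
limit is sought; observed pathology is the natural axis). Standard errors
come from the Jacobian-based covariance at the solution and the 95% CI on
the asymptote is Wald, `a ± 1.96·se`. Numerical choices that matter:

- *Initialization.* The heuristic start (`a₀ = max(predicted)`,
  `b₀ = min(predicted)`, `c₀ = 1/range(observed)`) is augmented with a
  profiled start: for fixed `c` the model is linear in `(a, b)`, so a
  120-point log-spaced sweep over `c` with a 2-parameter linear solve per
  point finds the best basin cheaply. Without this, LM reliably lands in the
  near-linear local minimum (`c → 0`, `a → ∞`) whenever most observations
  lie on the rising limb. Perturbed restarts handle remaining failures.
- *Degenerate inputs.* Essentially constant predictions (variance < 1e−8)
  fall back to the sample mean with the SE of the mean. Non-saturating data
  yield either a non-converged fit (`c ≤ 0`) or an asymptote far beyond the
  data, flagged `extrapolated` (asymptote more than one data-span above the
  largest prediction).
- *Data used.* The pipeline fits the ceiling on **all** participants'
  predictions rather than the held-out fifth alone: the plateau is carried
  by the minority of high-amyloid scans, and at n = 346 the 69-scan test set
  does not identify the asymptote. Error metrics, by contrast, are reported
  on held-out data only.

The error-vs-range table flags the Pareto set: analytes for which no
competitor has both lower global MAPE and larger predictive range.

## The synthetic cohort generator

The generator emulates the structure of a research cohort of older adults
with paired CSF and amyloid-PET:

- *Latent burden.* A 3-component mixture with weights (0.592, 0.11, 0.298)
  over the strata < 10 CL, 10–30 CL, > 30 CL; within strata, uniform(−5, 10),
  uniform(10, 30), and 30 + Exp(mean 35) truncated at 120 CL — a right-skewed
  positive tail as observed in amyloid cohorts.
- *Biomarkers.* Mean response
  `floor + direction·span·logistic(steepness·(min(latent, ceiling) − midpoint))`
  with additive Gaussian noise (optionally proportional to the mean). The
  response is exactly flat beyond the ceiling — the plateau is a hard
  property of the analyte, not of sampling.
- *Regions.* Each region follows
  `1 + (max_suvr − 1)·logistic(k·(latent − onset))` with `k = 4·rate/(max_suvr − 1)`
  (so `rate` is the SUVR/CL slope at mid-rise), plus a participant-level
  shared Gaussian term (same draw for every region, inducing the positive
  inter-regional covariance the multi-output forecaster exploits) and
  independent per-region noise. SUVR is clamped at 0.5.

### Calibration of the defaults

The default atlas spreads the 37 onsets from 15 CL (gyrus rectus, lateral
temporal — the regions that accumulate first) to 110 CL (rostral middle
frontal), with the seven summary regions at 25–110 CL and a common plateau
of 3.8 SUVR. This was calibrated so that the 7-region mean maps latent
burden approximately linearly onto observed Centiloids over 0–115 CL: with
narrower tiers the summary measure saturates by ~75 CL, which would collapse
the observable distinction between analytes whose ceilings differ above that
point — the very contrast the analysis studies. Qualitative staging
(temporal/orbitofrontal before precuneus/prefrontal) is preserved.

The three presets encode the analyte classes as simulation ground truth:

| preset | form | ceiling (CL) | noise character |
|---|---|---|---|
| pT217_T217-like | steep logistic (midpoint 30, steepness 0.09) | 63 | low (SD 0.35 on span 18) |
| pT231_T231-like | near-linear ramp (midpoint 60, steepness 0.035) | 87 | higher (SD 0.9 on span 14) |
| AB42_AB40-like | decreasing near-linear ramp (midpoint 55) | 85 | higher (SD 0.0035 on span 0.05) |

The noisy presets are deliberately near-linear rather than steeply
saturating: an analyte can only remain informative up to a high ceiling if
its local slope stays above its noise all the way there (noise/slope
< ~12 CL at the ceiling for both presets), while the same noise makes them
clearly worse than the pT217-like analyte at low burden. A steep logistic
with large noise would silently stop carrying signal 20–40 CL below its
nominal ceiling and fail to emulate the intended analyte class.

### What the generator does *not* emulate

Longitudinal trajectories and CSF–PET visit intervals (cohorts are
cross-sectional); covariate effects (age, sex, APOE) on biomarkers;
assay-specific measurement artifacts; heavy-tailed or heteroscedastic PET
noise (an optional proportional-noise flag exists for biomarkers). Passing
tests on synthetic cohorts therefore demonstrate that the pipeline's
machinery is correct and that its qualitative conclusions follow from the
assumed structure — not that real CSF assays have these exact parameters.

### Behaviour of ceiling estimates on synthetic cohorts

Two systematic effects are worth understanding when reading the demo output.
First, a forecaster's predictions for saturated participants converge to the
*conditional mean* of observed burden beyond the ceiling, so the estimated
asymptote sits above the generative ceiling (e.g. ~95 CL estimated for the
63-CL pT217-like preset at n = 346). Second, when an analyte's ceiling lies
near the cohort's maximum burden (the pT231-like preset at 87 CL in a cohort
reaching ~115 CL), the plateau is barely sampled and the asymptote is
weakly identified: estimates become arbitrarily large with correspondingly
enormous CIs, and are flagged `extrapolated`. The *ordering* of estimated
ranges matches the generating ceilings reliably (the property the end-to-end
tests assert); the absolute values at this cohort size do not, and the
reports say so rather than hiding it.

## Determinism and problem sizes

Every stochastic step takes a seed; the pipeline derives stage seeds by
hashing (master seed, analyte, stage), so adding an analyte never perturbs
another's results, and a rerun with the same config and master seed is
byte-identical. The bundled demo uses the cohort size the generator is
calibrated for (n = 346) with the default grid and 1000-iteration window
bootstraps; the Monte-Carlo coverage check for the asymptote CI uses 200
replicates at n = 300 with noise SD 0.05. Unit and property tests use
smaller cohorts and coarser grids chosen to exercise the same code paths.

## Known limitations

- Single-analyte inputs only; combining phosphorylation sites is out of scope.
- The asymptotic form is fixed; Michaelis–Menten or 4PL alternatives are not
  compared.
- Wald CIs on the asymptote are first-order; profile-likelihood intervals are
  a documented extension point.
- Window-level significance by CI non-overlap is conservative and makes no
  multiplicity correction across windows.
- The demo's absolute MAPE values depend on the generator's noise settings;
  only orderings and identities are asserted by tests.
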