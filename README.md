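# amyloidcast

Forecasting **continuous** amyloid-PET burden from a **single** CSF biomarker,
and characterizing what each biomarker can and cannot predict.

Fluid biomarkers of Alzheimer's disease — CSF tau phosphorylation occupancies
such as pT217/T217 and pT231/T231, or the Aβ42/Aβ40 ratio — are usually
evaluated against a dichotomized amyloid-PET status. That throws away most of
the information in the scan and hides a crucial property: some analytes track
pathology tightly at low burden but *plateau* early, while noisier analytes
keep responding through much higher burden. `amyloidcast` implements, as a
reusable and fully tested pipeline, the machinery needed to study this
tradeoff on continuous PET values:

- **Scale harmonization** — an affine SUVR ↔ Centiloid map
  (`CL = 45.0·SUVR − 47.5` by default, fitted to published anchor pairs), the
  mean cortical summary over seven bilateral regions, and the 1.42 SUVR
  positivity threshold.
- **Single-input, multi-output neural forecaster** — a feedforward network
  (1 analyte → 3 ReLU hidden layers with inverted dropout → 37 regional SUVR
  outputs, linear activation), trained for exactly 100 epochs of mini-batch
  ADAM on MSE, with coarse grid-search tuning and bootstrap ensembles.
  Because all 37 regional outputs are predicted jointly, the model exploits
  the covariance structure of regional amyloid accumulation.
- **Error profiling** — global and per-region MAPE
  (`100 · mean(|ŷ − y| / y)` on the SUVR scale), plus a 25-Centiloid sliding
  window along the predicted-burden axis with 1000-iteration participant
  bootstraps, so burden-dependent accuracy and analyte-vs-analyte
  significance (non-overlapping 95% bands) become visible.
- **Predictive ceiling** — the 3-parameter asymptotic regression
  `ŷ = a + (b − a)·e^(−c·y)` of predicted on observed mean cortical SUVR; the
  horizontal asymptote `a` (Wald 95% CI), converted to Centiloids, is the
  biomarker's maximum predictive range.
- **Synthetic cohort generator** — cohorts with the relevant statistical
  structure (3-stratum amyloid mixture, saturating noisy biomarker responses
  with analyte-specific ceilings, staged regional accumulation with a shared
  noise factor), so the entire pipeline is testable without any data access.

## Worked example

```bash
python examples/06_full_pipeline.py
```

simulates a 346-participant cohort with three preset analytes, runs the full
simulate → split → tune → train → evaluate → ceiling pipeline on a shared
80/20 split, and prints:

```
analyte         rho  MAPE%  <40CL%  range CL
pT217_T217    0.852    4.9     4.9      95.1
pT231_T231    0.729    8.3     7.6  120228.0
AB42_AB40    -0.710    7.6     7.2   95364.6
```

Reading this: the pT217-like analyte correlates most strongly with cortical
burden (Spearman ρ = 0.852) and forecasts it with the lowest error, both
globally (4.9%) and below 40 Centiloids — but its estimated predictive range
(95 CL, 95% CI 86–104) is the *smallest* of the panel, because its response
is generated to plateau at 63 CL of latent burden. The pT231-like analyte is
about twice as noisy at low burden yet keeps responding through 87 CL, so its
forecast ceiling lies beyond the range this cohort can even pin down (the
huge "range" values are flagged `extrapolated` in the tradeoff table: the
asymptote is not identified, only the ordering is). That ordering — precise
but early-saturating versus noisy but far-reaching — is the central tradeoff
the package quantifies. The other examples (`examples/01…05`) each exercise
one capability in isolation and print a line or two explaining their output.

There is also a thin CLI over the same library:

```bash
amyloidcast simulate --n 346 --seed 42 --out cohort.csv
amyloidcast run --config configs/demo.yaml --out scratch/demo_run
```

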