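# Bundled demo: a 346-participant synthetic cohort with the three preset
# analytes (pT217/T217-like, pT231/T231-like, AB42/AB40-like), the default
# 37-region atlas, the default coarse hyperparameter grid, and 1000-iteration
# window bootstraps.  Run with:
#   amyloidcast run --config configs/demo.yaml --out scratch/demo_run
n: 346
master_seed: 42
train_fraction: 0.8
window_width: 25.0
window_step: 1.0
n_boot: 1000
min_n: 10
window_axis: predicted
make_plots: true
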