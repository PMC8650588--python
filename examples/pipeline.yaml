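# Example configuration for `rhizodose run-all`.
# Omitted keys fall back to the study defaults (8 weeks, 50 replicates,
# all three species presets).
weeks: 4
n_replicates: 20
dt: 0.5
species: [pakchoi, lacinato]
fit_starts: 4
fit_maxfev: 400
opt_seeds: 3
opt_horizon: 504.0
opt_maxfev: 60
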