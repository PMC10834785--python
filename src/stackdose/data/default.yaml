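# stackdose default run configuration.
# Every stochastic stage derives its stream from the single top-level seed.

seed: 7

generator:
  n: 641            # cohort size
  # Marginal distributions default to the published 641-patient cohort
  # (see stackdose.cohort.GeneratorConfig); override any field here, e.g.:
  # age_mean: 46.6
  # noise_sd of the dose model (multiplicative lognormal):
  # dose_noise_sd: 0.12

split:
  test_fraction: 0.10   # reserved holdout fraction
  alpha: 0.05           # audit flagging level
  min_events: 5         # exclusion rule for rare binary flags

selection:
  method: bds           # none | filter | rfecv | bds
  filter_threshold: 0.10

stacking:
  variant: heuristic    # traditional | weighted | heuristic
  k: 5                  # cross-validation folds
  band: 0.20            # ERR band (relative error)
  pool: [RF, GBRT, GPR, SGD, KRR, Bayes, MLR, SVR]
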