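# Example run configuration for scedkit.
# Every command accepts this file via --config; command-line flags
# (e.g. --seed) override it.  Omitted keys fall back to the defaults
# shown here.

seed: 1                      # master seed for simulation and design draws

design_space:                # admissible randomized phase designs
  total_days: 96             # fixed length of each participant's course
  treatment_days: 56         # phase B length (8 weeks)
  baseline_min: 7            # shortest admissible baseline (phase A)
  baseline_max: 26           # longest admissible baseline
  strata:                    # baseline randomization strata (inclusive)
    - [7, 11]
    - [12, 19]
    - [20, 26]

generator:                   # synthetic daily-outcome process (0-27 scale)
  baseline_level: 12.0       # expected anxiety sum during baseline
  effect_size: 9.0           # total expected drop once the effect is complete
  onset_delay_days: 21       # days after treatment entry before any effect
  ramp_days: 28              # days over which the effect accrues linearly
  ar_coefficient: 0.5        # lag-1 autocorrelation of the latent process
  noise_sd: 3.0              # innovation SD of the latent AR(1) noise
  missing_rate: 0.237        # daily probability of a missing response (MCAR)
  effect_shape: ramp         # "ramp" (delayed, gradual) or "step"

analysis:
  outcome: anxiety           # outcome the randomization test runs on
  direction: greater         # one-sided: MeanA - MeanBC large = improvement
                             # ("less" and "two_sided" also available)
  scenario_set: all          # "all" 20 entries, or "stratum" (sensitivity)
  ties: no_overlap           # POD points tied with the extreme do not overlap
  trend_method: ols          # "ols" or "split_middle" within-phase trend
  tau_u_variant: trend_corrected   # or "simple" (no baseline-trend penalty)
  immediacy_window: 3        # points on each side of the phase boundary
  reverse_item5: false       # arithmetically flip value-based action (9 - x)
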