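# Cohort preset emulating a ~120-person spacefarer corps followed ~25 years
# on average; higher all-cause mortality and a CVD-dominated death mix.
#
# Tuning as in astronaut_like.yaml: L and the horizon lower bound solved so
# that expected deaths = 36 of n = 117 and mean follow-up = 25.4 years with
# maximum 54.9; hazards split L in proportion 10 : 18 : 2 : 6.
label: cosmonaut_like
n: 117
hazards:
  cancer: 0.00336496
  cvd: 0.00605694
  other_natural: 0.00067299
  external: 0.00201898
censor_time: [8.0237, 54.9]
frailty_variance: 0.0
seed: 0
calibration_targets:
  expected_deaths: 36
  death_mix: {cancer: 10, cvd: 18, other_natural: 2, external: 6}
  mean_follow_up_years: 25.4
  max_follow_up_years: 54.9
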