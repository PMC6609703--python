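# Cohort preset emulating a ~300-person spacefarer corps followed ~24 years
# on average with administrative censoring at a study close date.
#
# Tuning: with per-subject horizons C ~ Uniform(a, b) and total hazard L,
# mean follow-up = P(death)/L and P(death) = 1 - (e^{-La} - e^{-Lb})/(L(b-a)).
# L and a were solved so that expected deaths = 53 of n = 301 and mean
# follow-up = 24.2 years with maximum 54.8; cause-specific hazards split L
# in proportion 16 : 8 : 9 : 20 (unknown-cause deaths folded into other
# natural, the base-case reassignment).
label: astronaut_like
n: 301
hazards:
  cancer: 0.00219653
  cvd: 0.00109827
  other_natural: 0.00123555
  external: 0.00274567
censor_time: [0.2408, 54.8]
frailty_variance: 0.0
seed: 0
calibration_targets:
  expected_deaths: 53
  death_mix: {cancer: 16, cvd: 8, other_natural: 9, external: 20}
  mean_follow_up_years: 24.2
  max_follow_up_years: 54.8
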