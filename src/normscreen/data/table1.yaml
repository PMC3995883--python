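# Default cohort configuration: group-level moments of the validation
# study's screened memory-clinic sample.
#
# The control group's delayed story recall (DSR) is generated from the
# published norming regression (expected DSR = 31.535 + 0.746*education
# - 0.206*age); its residual SD is derived so the marginal DSR SD equals
# the published 8.49: sqrt(8.49^2 - (0.746*3.30)^2 - (0.206*8.87)^2).
# The vascular (VaD) and other-dementia groups reuse the published
# "all types of dementia" row (no separate rows are published for them).
seed: 20140310
mmse_dsr_partial_r: 0.575
isr_dsr_rho: 0.9
retest:
  group: MCI
  fraction: 0.417910   # 56 of 134 MCI subjects re-tested at 3 months
  r: 0.887
nc_regression:
  intercept: 31.535
  beta_edu: 0.746
  beta_age: -0.206
  residual_sd: 7.9171
groups:
  - label: NC
    n: 249
    age_mean: 66.94
    age_sd: 8.87
    edu_mean: 12.89
    edu_sd: 3.30
    mmse_mean: 28.41
    mmse_sd: 1.50
    isr_mean: 30.03
    isr_sd: 8.58
    dsr_mean: 26.60
    dsr_sd: 8.49
    hamd_mean: 3.78
    hamd_sd: 3.30
    male_frac: 0.6345   # 158 / 249
  - label: MCI
    n: 134
    age_mean: 69.91
    age_sd: 8.38
    edu_mean: 11.32
    edu_sd: 3.84
    mmse_mean: 26.98
    mmse_sd: 2.04
    isr_mean: 13.91
    isr_sd: 8.79
    dsr_mean: 9.40
    dsr_sd: 8.88
    hamd_mean: 3.84
    hamd_sd: 3.12
    male_frac: 0.5672   # 76 / 134
  - label: AD
    n: 97
    age_mean: 71.09
    age_sd: 9.04
    edu_mean: 10.63
    edu_sd: 4.49
    mmse_mean: 15.69
    mmse_sd: 5.91
    isr_mean: 4.02
    isr_sd: 6.06
    dsr_mean: 1.60
    dsr_sd: 4.58
    hamd_mean: 2.42
    hamd_sd: 2.12
    male_frac: 0.5567   # 54 / 97
  - label: VaD
    n: 14
    age_mean: 70.93
    age_sd: 9.15
    edu_mean: 10.55
    edu_sd: 4.39
    mmse_mean: 16.28
    mmse_sd: 6.06
    isr_mean: 4.49
    isr_sd: 5.964
    dsr_mean: 1.63
    dsr_sd: 4.315
    hamd_mean: 2.78
    hamd_sd: 2.47
    male_frac: 0.5031
  - label: other_dementia
    n: 50
    age_mean: 70.93
    age_sd: 9.15
    edu_mean: 10.55
    edu_sd: 4.39
    mmse_mean: 16.28
    mmse_sd: 6.06
    isr_mean: 4.49
    isr_sd: 5.964
    dsr_mean: 1.63
    dsr_sd: 4.315
    hamd_mean: 2.78
    hamd_sd: 2.47
    male_frac: 0.5031
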