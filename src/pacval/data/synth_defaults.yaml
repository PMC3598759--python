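# Default synthetic linked-cohort configuration, version 1.
#
# The defaults emulate the published study conditions of an eight-year
# state-wide obstetric cohort: per-group registry incidence, per-group
# hospital capture probability, hospitalisation multiplicity (all/index
# admission ratios), admission-versus-registration timing mixture,
# false-positive mechanism rates, and probabilistic-linkage error rates.
version: 1
seed: 0
n_women: 470277
study_start: 2001-01-01
study_end: 2008-12-31
# distribution of maternities per woman over the study period (mean 1.445,
# matching 679,736 maternities among 470,277 women)
maternities_per_woman: {1: 0.62, 2: 0.32, 3: 0.055, 4: 0.005}
min_interdelivery_days: 301
# completed weeks of gestation at delivery (births of >= 20 weeks only)
gestation_weeks:
  20: 0.0005
  21: 0.0004
  22: 0.0004
  23: 0.0004
  24: 0.0005
  25: 0.0006
  26: 0.0008
  27: 0.0009
  28: 0.0010
  29: 0.0012
  30: 0.0015
  31: 0.0018
  32: 0.0030
  33: 0.0050
  34: 0.0080
  35: 0.0130
  36: 0.0240
  37: 0.0700
  38: 0.1700
  39: 0.2600
  40: 0.2980
  41: 0.1250
  42: 0.0120
  43: 0.0015
  44: 0.0005
# incident registry cancers per 100,000 maternities, by clinical group
group_incidence_per_100k:
  melanoma: 47.4
  breast: 32.1
  thyroid_endocrine: 19.6
  gynaecological: 13.8
  lymphohaematopoeitic: 12.8
  colorectal: 5.1
  neurological: 3.2
  bone_connective: 2.8
  head_neck: 2.1
  upper_gi: 2.6
  respiratory: 1.0
  ill_defined_unknown: 1.6
  urogenital: 1.2
# probability that an incident cancer produces at least one in-window
# cancer-coded hospital admission (the per-group hospital sensitivity)
capture_prob:
  melanoma: 0.361
  breast: 0.629
  thyroid_endocrine: 0.786
  gynaecological: 0.778
  lymphohaematopoeitic: 0.721
  colorectal: 0.643
  neurological: 0.909
  bone_connective: 0.889
  head_neck: 0.692
  upper_gi: 0.833
  respiratory: 1.0
  ill_defined_unknown: 0.50
  urogenital: 1.0
# mean number of repeat admissions beyond the index admission for a captured
# cancer (Poisson); set to the all/index hospitalisation ratio minus one
extra_admissions_mean:
  melanoma: 0.183
  breast: 2.230
  thyroid_endocrine: 0.664
  gynaecological: 0.988
  lymphohaematopoeitic: 2.091
  colorectal: 1.000
  neurological: 1.375
  bone_connective: 1.560
  head_neck: 0.182
  upper_gi: 1.385
  respiratory: 0.889
  ill_defined_unknown: 0.833
  urogenital: 0.727
# calendar-month offset of the index admission before the registry
# registration date among true positives
timing_mixture:
  same_month: 0.66
  prior_1_2: 0.28
  prior_3_5: 0.05
  prior_6_plus: 0.01
  after_registration: 0.0
# false-positive mechanisms, as per-maternity planting probabilities
fp_prevalent_rate: 1.2652e-4     # 86 prevalent FPs per 679,736 maternities
fp_prevalent_counts:             # group split of prevalent FPs; "other"
  lymphohaematopoeitic: 38       # spreads over the remaining groups in
  breast: 14                     # proportion to registry incidence
  melanoma: 13
  thyroid_endocrine: 10
  other: 11
fp_miscode_rate: 3.2365e-5       # 22 miscoded cancers per 679,736 maternities
miscode_sources:                 # true group -> coded-group confusion
  colorectal: {weight: 7, targets: {upper_gi: 1.0}}
  melanoma: {weight: 3, targets: {breast: 0.5, bone_connective: 0.5}}
  gynaecological: {weight: 4, targets: {upper_gi: 1.0}}
  other: {weight: 8}             # source by incidence, target uniform-other
fp_noise_rate: 8.5327e-5         # 58 unexplained FPs per 679,736 maternities
fp_noise_counts:                 # group split of noise admissions (overall
  melanoma: 29                   # false-positive group distribution)
  breast: 20
  thyroid_endocrine: 15
  gynaecological: 15
  lymphohaematopoeitic: 48
  colorectal: 11
  neurological: 4
  bone_connective: 7
  head_neck: 2
  upper_gi: 5
  respiratory: 3
  ill_defined_unknown: 4
  urogenital: 3
# probabilistic record-linkage quality (registry side)
linkage_missed_rate: 0.005       # < 5 in 1,000 missed links
linkage_false_rate: 0.003        # < 3 in 1,000 false links
# registry notification history reaches back to this horizon
lookback_start: 1994-01-01
include_delivery_admissions: true
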