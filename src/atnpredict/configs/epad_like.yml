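# Synthetic-cohort configuration reproducing the published cohort structure:
# 1500 participants, exclusion cascade 82 (dementia/MCI dx) + 171 (CDR >= 0.5)
# + 237 (missing ATN biomarker) leaving 1010 analytic participants in five
# ATN groups (567/211/67/31/134), with group-specific covariate marginals.
# The within-group split of the AD (N+/-) and non-AD (three combinations)
# groups is a consistent completion of the published A+/T+/N+ marginals
# (309/158/90); see docs/methods.md.
seed: 0
site_count: 21
combination_counts:
  A-T-N-: 567
  A+T-N-: 211
  A+T+N-: 57
  A+T+N+: 10
  A+T-N+: 31
  A-T+N-: 85
  A-T+N+: 6
  A-T-N+: 43
exclusion_counts:
  dementia_mci: 82
  cdr: 171
  missing_atn: 237
abeta_cutoff: 1025.0
ptau_cutoff: 24.0
abeta_margin_scale: 220.0
ptau_margin_scale: 6.0
group_marginals:
  normal_ad_biomarkers:
    age: [63.6, 6.6]
    female_p: 0.601
    education: [14.8, 3.7]
    apoe4_p: 0.322
    family_history_p: 0.721
    systolic_bp: [133.5, 17.6]
    bmi: [26.4, 4.3]
    high_cholesterol_p: 0.173
    physical_inactivity_p: 0.433
    ever_smoked_p: 0.521
    bp_medication_p: 0.176
    diabetes_p: 0.049
    prior_cvd_p: 0.037
    atrial_fibrillation_p: 0.016
    wml: [9.3, 26.2]
    mmse: [28.9, 1.3]
    rbans_list_learning: [29.4, 4.2]
    rbans_coding: [47.5, 9.9]
  alzheimers_pathologic_change:
    age: [64.7, 7.1]
    female_p: 0.540
    education: [14.9, 3.7]
    apoe4_p: 0.475
    family_history_p: 0.692
    systolic_bp: [136.4, 17.9]
    bmi: [26.5, 4.3]
    high_cholesterol_p: 0.147
    physical_inactivity_p: 0.383
    ever_smoked_p: 0.531
    bp_medication_p: 0.133
    diabetes_p: 0.019
    prior_cvd_p: 0.028
    atrial_fibrillation_p: 0.014
    wml: [17.3, 35.2]
    mmse: [28.9, 1.2]
    rbans_list_learning: [29.0, 4.2]
    rbans_coding: [45.5, 10.4]
  alzheimers_disease:
    age: [69.1, 5.9]
    female_p: 0.567
    education: [13.9, 3.8]
    apoe4_p: 0.692
    family_history_p: 0.866
    systolic_bp: [137.8, 17.0]
    bmi: [24.8, 3.7]
    high_cholesterol_p: 0.119
    physical_inactivity_p: 0.433
    ever_smoked_p: 0.582
    bp_medication_p: 0.134
    diabetes_p: 0.060
    prior_cvd_p: 0.045
    atrial_fibrillation_p: 0.015
    wml: [27.8, 48.5]
    mmse: [28.2, 1.9]
    rbans_list_learning: [27.4, 4.5]
    rbans_coding: [41.6, 9.5]
  ad_and_non_ad_pathologic_change:
    age: [62.4, 7.1]
    female_p: 0.516
    education: [15.8, 3.5]
    apoe4_p: 0.367
    family_history_p: 0.613
    systolic_bp: [136.9, 18.1]
    bmi: [27.2, 4.5]
    high_cholesterol_p: 0.097
    physical_inactivity_p: 0.367
    ever_smoked_p: 0.600
    bp_medication_p: 0.161
    diabetes_p: 0.0
    prior_cvd_p: 0.065
    atrial_fibrillation_p: 0.0
    wml: [24.1, 42.8]
    mmse: [29.0, 1.3]
    rbans_list_learning: [29.7, 3.6]
    rbans_coding: [47.5, 11.8]
  non_ad_pathologic_change:
    age: [66.7, 6.2]
    female_p: 0.605
    education: [14.5, 3.6]
    apoe4_p: 0.349
    family_history_p: 0.612
    systolic_bp: [136.0, 18.8]
    bmi: [26.2, 4.6]
    high_cholesterol_p: 0.172
    physical_inactivity_p: 0.459
    ever_smoked_p: 0.594
    bp_medication_p: 0.157
    diabetes_p: 0.082
    prior_cvd_p: 0.052
    atrial_fibrillation_p: 0.037
    wml: [11.2, 27.8]
    mmse: [28.6, 1.2]
    rbans_list_learning: [28.5, 4.3]
    rbans_coding: [44.3, 11.2]
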