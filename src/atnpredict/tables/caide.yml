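# CAIDE mid-life dementia risk score, non-APOE variant (Kivipelto et al. 2006,
# Lancet Neurol; the paper's cited source for the component list).
# Adaptation: the total-cholesterol > 6.5 mmol/L criterion is replaced by
# self-reported hypercholesterolaemia, which scores the same 2 points.
#
# Band convention: numeric bands are half-open [low, high). The source's
# inclusive wording maps to these boundaries as follows: "age 47-53" ->
# [47, 54); "education 7-9 years" -> [7, 10); "SBP > 140" -> [140, inf);
# "BMI > 30" -> [30, inf). Ranges outside the source's printed bands fall
# in the nearest boundary band.
score_name: caide
sex_specific: false
provenance: caide_kivipelto_2006_non_apoe
components:
  - name: age
    field: age
    sex: both
    kind: numeric
    range: [0, 130]
    bands:
      - {low: 0, high: 47, points: 0}
      - {low: 47, high: 54, points: 3}
      - {low: 54, high: 130, points: 4}
  - name: education
    field: education_years
    sex: both
    kind: numeric
    range: [0, 40]
    bands:
      - {low: 0, high: 7, points: 3}
      - {low: 7, high: 10, points: 2}
      - {low: 10, high: 40, points: 0}
  - name: sex
    field: sex_female
    sex: both
    kind: flag
    points_true: 0
    points_false: 1
  - name: systolic_bp
    field: systolic_bp
    sex: both
    kind: numeric
    range: [0, 400]
    bands:
      - {low: 0, high: 140, points: 0}
      - {low: 140, high: 400, points: 2}
  - name: bmi
    field: bmi
    sex: both
    kind: numeric
    range: [0, 100]
    bands:
      - {low: 0, high: 30, points: 0}
      - {low: 30, high: 100, points: 2}
  - name: cholesterol
    field: high_cholesterol
    sex: both
    kind: flag
    points_true: 2
    points_false: 0
  - name: physical_inactivity
    field: physical_inactivity
    sex: both
    kind: flag
    points_true: 1
    points_false: 0
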