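# Framingham general cardiovascular disease risk score, sex-specific point
# system (D'Agostino et al. 2008, Circulation; the paper's cited source).
# Adaptation: in place of the total- and HDL-cholesterol components, the
# source's diabetes points are applied to self-reported
# hypercholesterolaemia (component "cholesterol" below).
#
# Band convention: half-open [low, high); ages below the source's printed
# range (30-34 is the lowest band) score 0; SBP bands carry the source's
# negative points for untreated SBP < 120 mmHg, so totals can be negative
# for very low-risk profiles. Treated/untreated SBP bands are selected by
# the bp_medication flag.
score_name: framingham_cvd
sex_specific: true
provenance: framingham_general_cvd_dagostino_2008
components:
  - name: age
    field: age
    sex: female
    kind: numeric
    range: [0, 130]
    bands:
      - {low: 0, high: 35, points: 0}
      - {low: 35, high: 40, points: 2}
      - {low: 40, high: 45, points: 4}
      - {low: 45, high: 50, points: 5}
      - {low: 50, high: 55, points: 7}
      - {low: 55, high: 60, points: 8}
      - {low: 60, high: 65, points: 9}
      - {low: 65, high: 70, points: 10}
      - {low: 70, high: 75, points: 11}
      - {low: 75, high: 130, points: 12}
  - name: age
    field: age
    sex: male
    kind: numeric
    range: [0, 130]
    bands:
      - {low: 0, high: 35, points: 0}
      - {low: 35, high: 40, points: 2}
      - {low: 40, high: 45, points: 5}
      - {low: 45, high: 50, points: 6}
      - {low: 50, high: 55, points: 8}
      - {low: 55, high: 60, points: 10}
      - {low: 60, high: 65, points: 11}
      - {low: 65, high: 70, points: 12}
      - {low: 70, high: 75, points: 14}
      - {low: 75, high: 130, points: 15}
  - name: systolic_bp
    field: systolic_bp
    sex: female
    kind: numeric
    condition: {field: bp_medication, value: false}
    range: [0, 400]
    bands:
      - {low: 0, high: 120, points: -3}
      - {low: 120, high: 130, points: 0}
      - {low: 130, high: 140, points: 1}
      - {low: 140, high: 150, points: 2}
      - {low: 150, high: 160, points: 4}
      - {low: 160, high: 400, points: 5}
  - name: systolic_bp
    field: systolic_bp
    sex: female
    kind: numeric
    condition: {field: bp_medication, value: true}
    range: [0, 400]
    bands:
      - {low: 0, high: 120, points: -1}
      - {low: 120, high: 130, points: 2}
      - {low: 130, high: 140, points: 3}
      - {low: 140, high: 150, points: 5}
      - {low: 150, high: 160, points: 6}
      - {low: 160, high: 400, points: 7}
  - name: systolic_bp
    field: systolic_bp
    sex: male
    kind: numeric
    condition: {field: bp_medication, value: false}
    range: [0, 400]
    bands:
      - {low: 0, high: 120, points: -2}
      - {low: 120, high: 130, points: 0}
      - {low: 130, high: 140, points: 1}
      - {low: 140, high: 160, points: 2}
      - {low: 160, high: 400, points: 3}
  - name: systolic_bp
    field: systolic_bp
    sex: male
    kind: numeric
    condition: {field: bp_medication, value: true}
    range: [0, 400]
    bands:
      - {low: 0, high: 120, points: 0}
      - {low: 120, high: 130, points: 2}
      - {low: 130, high: 140, points: 3}
      - {low: 140, high: 160, points: 4}
      - {low: 160, high: 400, points: 5}
  - name: smoking
    field: ever_smoked
    sex: female
    kind: flag
    points_true: 3
    points_false: 0
  - name: smoking
    field: ever_smoked
    sex: male
    kind: flag
    points_true: 4
    points_false: 0
  - name: diabetes
    field: diabetes
    sex: female
    kind: flag
    points_true: 4
    points_false: 0
  - name: diabetes
    field: diabetes
    sex: male
    kind: flag
    points_true: 3
    points_false: 0
  - name: cholesterol
    field: high_cholesterol
    sex: female
    kind: flag
    points_true: 4
    points_false: 0
  - name: cholesterol
    field: high_cholesterol
    sex: male
    kind: flag
    points_true: 3
    points_false: 0
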