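# Framingham stroke risk profile, sex-specific point system (D'Agostino
# et al. 1994, Stroke; the paper's cited source). Components: age, systolic
# BP with antihypertensive-treatment adjustment, diabetes, smoking, prior
# CVD, atrial fibrillation, left-ventricular hypertrophy.
#
# Band convention: half-open [low, high). The source table starts at age 54
# and SBP 97 (men) / 95 (women); values below fall in the lowest (0-point)
# band, values above the top band take its points. The women's treatment
# adjustment varies with SBP in the source; it is encoded here as a separate
# treated band set whose points equal the untreated points plus the
# SBP-specific treatment increment. Men's treated bands are untreated + 2.
score_name: framingham_stroke
sex_specific: true
provenance: framingham_stroke_dagostino_1994
components:
  - name: age
    field: age
    sex: male
    kind: numeric
    range: [0, 130]
    bands:
      - {low: 0, high: 57, points: 0}
      - {low: 57, high: 60, points: 1}
      - {low: 60, high: 63, points: 2}
      - {low: 63, high: 66, points: 3}
      - {low: 66, high: 69, points: 4}
      - {low: 69, high: 73, points: 5}
      - {low: 73, high: 76, points: 6}
      - {low: 76, high: 79, points: 7}
      - {low: 79, high: 82, points: 8}
      - {low: 82, high: 85, points: 9}
      - {low: 85, high: 130, points: 10}
  - name: age
    field: age
    sex: female
    kind: numeric
    range: [0, 130]
    bands:
      - {low: 0, high: 57, points: 0}
      - {low: 57, high: 60, points: 1}
      - {low: 60, high: 63, points: 2}
      - {low: 63, high: 65, points: 3}
      - {low: 65, high: 68, points: 4}
      - {low: 68, high: 71, points: 5}
      - {low: 71, high: 74, points: 6}
      - {low: 74, high: 77, points: 7}
      - {low: 77, high: 79, points: 8}
      - {low: 79, high: 82, points: 9}
      - {low: 82, high: 130, points: 10}
  - name: systolic_bp
    field: systolic_bp
    sex: male
    kind: numeric
    condition: {field: bp_medication, value: false}
    range: [0, 400]
    bands:
      - {low: 0, high: 106, points: 0}
      - {low: 106, high: 116, points: 1}
      - {low: 116, high: 126, points: 2}
      - {low: 126, high: 136, points: 3}
      - {low: 136, high: 146, points: 4}
      - {low: 146, high: 156, points: 5}
      - {low: 156, high: 166, points: 6}
      - {low: 166, high: 176, points: 7}
      - {low: 176, high: 186, points: 8}
      - {low: 186, high: 196, points: 9}
      - {low: 196, high: 400, points: 10}
  - name: systolic_bp
    field: systolic_bp
    sex: male
    kind: numeric
    condition: {field: bp_medication, value: true}
    range: [0, 400]
    bands:
      - {low: 0, high: 106, points: 2}
      - {low: 106, high: 116, points: 3}
      - {low: 116, high: 126, points: 4}
      - {low: 126, high: 136, points: 5}
      - {low: 136, high: 146, points: 6}
      - {low: 146, high: 156, points: 7}
      - {low: 156, high: 166, points: 8}
      - {low: 166, high: 176, points: 9}
      - {low: 176, high: 186, points: 10}
      - {low: 186, high: 196, points: 11}
      - {low: 196, high: 400, points: 12}
  - name: systolic_bp
    field: systolic_bp
    sex: female
    kind: numeric
    condition: {field: bp_medication, value: false}
    range: [0, 400]
    bands:
      - {low: 0, high: 105, points: 0}
      - {low: 105, high: 115, points: 1}
      - {low: 115, high: 125, points: 2}
      - {low: 125, high: 135, points: 3}
      - {low: 135, high: 145, points: 4}
      - {low: 145, high: 155, points: 5}
      - {low: 155, high: 165, points: 6}
      - {low: 165, high: 175, points: 7}
      - {low: 175, high: 185, points: 8}
      - {low: 185, high: 195, points: 9}
      - {low: 195, high: 400, points: 10}
  - name: systolic_bp
    field: systolic_bp
    sex: female
    kind: numeric
    condition: {field: bp_medication, value: true}
    range: [0, 400]
    bands:
      - {low: 0, high: 105, points: 6}
      - {low: 105, high: 115, points: 6}
      - {low: 115, high: 125, points: 7}
      - {low: 125, high: 135, points: 7}
      - {low: 135, high: 145, points: 7}
      - {low: 145, high: 155, points: 8}
      - {low: 155, high: 165, points: 8}
      - {low: 165, high: 175, points: 8}
      - {low: 175, high: 185, points: 9}
      - {low: 185, high: 195, points: 9}
      - {low: 195, high: 400, points: 10}
  - name: diabetes
    field: diabetes
    sex: male
    kind: flag
    points_true: 2
    points_false: 0
  - name: diabetes
    field: diabetes
    sex: female
    kind: flag
    points_true: 3
    points_false: 0
  - name: smoking
    field: ever_smoked
    sex: male
    kind: flag
    points_true: 3
    points_false: 0
  - name: smoking
    field: ever_smoked
    sex: female
    kind: flag
    points_true: 3
    points_false: 0
  - name: prior_cvd
    field: prior_cvd
    sex: male
    kind: flag
    points_true: 4
    points_false: 0
  - name: prior_cvd
    field: prior_cvd
    sex: female
    kind: flag
    points_true: 2
    points_false: 0
  - name: atrial_fibrillation
    field: atrial_fibrillation
    sex: male
    kind: flag
    points_true: 4
    points_false: 0
  - name: atrial_fibrillation
    field: atrial_fibrillation
    sex: female
    kind: flag
    points_true: 6
    points_false: 0
  - name: lvh
    field: left_ventricular_hypertrophy
    sex: male
    kind: flag
    points_true: 5
    points_false: 0
  - name: lvh
    field: left_ventricular_hypertrophy
    sex: female
    kind: flag
    points_true: 4
    points_false: 0
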