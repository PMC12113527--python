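# Shipped triage guideline rule sets.
#
# Each rule set is a disjunction: any criterion met classifies the patient
# as severe trauma.  CURRENT_* are the standard physiological field-triage
# criteria evaluated at the prehospital assessment (1), the in-hospital
# assessment (2), or either (3).  ALTERNATIVE is the eight-criterion
# age-adapted guideline with static thresholds evaluated at either
# assessment and two transport-interval (delta) criteria.
CURRENT_1:
  name: CURRENT_1
  positive_label_meaning: severe trauma
  criteria:
    - {op: lt, variable: sbp, threshold: 90, assessment: prehospital}
    - {op: outside, variable: rr, low: 10, high: 29, assessment: prehospital}
    - {op: avpu_le, level: V, assessment: prehospital}
CURRENT_2:
  name: CURRENT_2
  positive_label_meaning: severe trauma
  criteria:
    - {op: lt, variable: sbp, threshold: 90, assessment: inhospital}
    - {op: outside, variable: rr, low: 10, high: 29, assessment: inhospital}
    - {op: avpu_le, level: V, assessment: inhospital}
CURRENT_3:
  name: CURRENT_3
  positive_label_meaning: severe trauma
  criteria:
    - {op: lt, variable: sbp, threshold: 90, assessment: either}
    - {op: outside, variable: rr, low: 10, high: 29, assessment: either}
    - {op: avpu_le, level: V, assessment: either}
ALTERNATIVE:
  name: ALTERNATIVE
  positive_label_meaning: severe trauma
  criteria:
    - {op: lt, variable: sbp, threshold: 106, assessment: either}
    - {op: lt, variable: spo2, threshold: 91, assessment: either}
    - {op: outside, variable: rr, low: 8, high: 22, assessment: either}
    - {op: lt, variable: pr, threshold: 52, assessment: either}
    - {op: avpu_le, level: V, assessment: either}
    - {op: avpu_trans, from_level: A, to_level: U, assessment: delta}
    - {op: delta_ge, variable: sbp, threshold: 60, mode: absolute, assessment: delta}
    - {op: delta_ge, variable: pr, threshold: 44, mode: signed, assessment: delta}
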