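# fieldtriage

Age-specific trauma field-triage rule induction and evaluation from paired
prehospital / in-hospital vital signs.

## The problem

Field triage decides, at the scene, whether an injured patient needs a
high-level trauma center.  The standard physiological criteria — systolic
blood pressure (SBP) < 90 mmHg, respiratory rate (RR) < 10 or > 29 /min, or
consciousness at "V" or lower on the AVPU scale — are tuned to the average
adult.  Adults aged 65 and older mount a blunted physiological response to
injury (relative hypotension in chronic hypertensives, beta-blocked heart
rates, and so on), so they are systematically **undertriaged**: truly severe
patients are missed.  An undertriage rate below 5 % and an overtriage rate
of 25–50 % are the usually quoted acceptability bands.

`fieldtriage` is a pipeline for building and evaluating *interpretable*
age-specific triage rules from patient-level records that carry the same
six vitals (SBP, DBP, PR, RR, BT, SpO2) and AVPU measured twice — once at
the first fire-department assessment and again at hospital arrival — plus
binary outcomes (ICU admission; in-hospital death).

## The method

A triage **rule set** is a disjunction of threshold predicates: the patient
is severe if *any* criterion fires.  Criteria may look at either assessment
or at the transport-interval change Δx = x_prehospital − x_inhospital
(e.g. "PR decrease ≥ 44 /min", "|ΔSBP| ≥ 60 mmHg", "alert → unresponsive").

Rule induction is sequential model-based (Bayesian) optimization over a
mixed space of per-criterion inclusion flags and thresholds.  The objective
is the cross-validated **F2 score**,

    F_beta = (1 + beta²) · P · R / (beta² · P + R),   beta = 2,

which weights recall (sensitivity) four times as heavily as precision and
therefore penalizes undertriage, the clinically expensive error for a rare
positive class.  Candidate rule sets are scored by mean held-out F2 over
5 stratified folds of the 70 % training split, and the winner is evaluated
once on the untouched 30 % test split, separately for the age ≥ 65 and
age < 65 strata.

Because the underlying EMS registry is not publicly distributable, the
package ships a calibrated synthetic-cohort generator (`synthetic_cohort`)
that reproduces the marginal vital-sign means/SDs, AVPU frequencies and
outcome prevalences of a metropolitan EMS trauma population, injects
controlled missingness/outlier artifacts to exercise the eligibility
filters, and ties outcomes to derangement features so that rule-based
signal exists by construction.

## Worked example

```python
from fieldtriage import synthetic_cohort as sc
from fieldtriage.rules import guideline_constants
from fieldtriage.report import compare_guidelines, wide_frame

spec = sc.CohortSpec(n=50_000, seed=1, missing_rate=0.0, outlier_rate=0.0)
cohort = sc.generate_cohort(spec)
results = compare_guidelines(guideline_constants(), cohort, outcomes=("icu",))
table = wide_frame(results)
print(table[table["stratum"] == "age>=65"].to_string(index=False))
```

prints

```
outcome stratum subset      metric  ALTERNATIVE  CURRENT_1  CURRENT_2  CURRENT_3
    icu age>=65    all           n    21810.000  21810.000  21810.000  21810.000
    icu age>=65    all sensitivity        0.782      0.382      0.471      0.489
    icu age>=65    all specificity        0.556      0.880      0.863      0.851
    icu age>=65    all   precision        0.164      0.262      0.276      0.268
    icu age>=65    all          f1        0.271      0.311      0.348      0.346
    icu age>=65    all          f2        0.446      0.350      0.413      0.419
    icu age>=65    all    accuracy        0.579      0.831      0.824      0.815
```

`CURRENT_1/2/3` are the standard criteria applied at the prehospital,
in-hospital, or either assessment; `ALTERNATIVE` is the shipped
eight-criterion age-adapted guideline (SBP < 106, SpO2 < 91 %, RR < 8 or
> 22, PR < 52, AVPU ≤ V, A→U deterioration, |ΔSBP| ≥ 60, ΔPR ≥ 44).  On
this synthetic elderly stratum the alternative guideline doubles
sensitivity (0.782 vs 0.382) — i.e. undertriage falls from 62 % to 22 % —
at the cost of specificity, and wins on the recall-weighted F2.  That is
the qualitative trade the age-adapted criteria are designed to make.

The same pipeline is scriptable end to end:

```sh
fieldtriage all --n 20000 --seed 7 --outdir run/
```

chains simulate → preprocess (eligibility filters, exclusion-flow report)
→ 70/30 stratified split → threshold optimization on the elderly training
stratum → guideline comparison on the test split → injury-severity (ISS ≥
16) and injury-type subgroup tables.

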