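# Methods

This note documents the models and procedures implemented by
`fieldtriage`, the parameters that matter, and the choices made where the
design was genuinely open.

## Data model

A cohort is a table with one row per transported trauma patient: age, sex,
six vitals (SBP, DBP mmHg; PR beats/min; RR breaths/min; BT °C; SpO2 %)
and the ordered AVPU consciousness scale (Alert > Verbal > Pain >
Unresponsive), each measured at the first fire-department assessment
(`_1`) and again in hospital (`_2`); optional per-region AIS severity
codes (1–6) with the derived Injury Severity Score; injury-type labels;
and two binary outcomes (ICU admission, in-hospital death).  Missing
values are empty CSV cells; the canonical in-memory container is a pandas
DataFrame, with a frozen `PatientRecord` dataclass as the record-level
view.

ISS is the sum of squares of the three highest AIS codes.  Any AIS of 6
pins the ISS at its maximum of 75 — the standard convention, implemented
behind a flag (`max_ais_six_is_75`, default on, logged when triggered)
because some published descriptions omit it.

## Eligibility filters

Records missing any key vital (SBP, DBP, BT, PR, RR, SpO2) at either
assessment are excluded first; then records with a value strictly beyond a
plausibility bound (SBP or DBP > 300 mmHg, BT > 50 or < 20 °C, PR > 300
/min, RR > 50 /min, SpO2 > 100 or < 30 %).  All comparisons are strict, so
boundary values (SpO2 = 100, BT = 20, RR = 50) are kept.  Bounds are
applied to *both* assessments: an implausible value at either invalidates
the measurement pair that the delta features are computed from.  Filters
are non-mutating partitions and the stage-by-stage exclusion flow is
emitted as a table.

## Rule sets

A rule set is a disjunction of criteria; any firing criterion classifies
the patient severe.  Criterion kinds: strict below/above thresholds,
two-sided "outside" ranges, AVPU at-or-below a level, a specific AVPU
transition between assessments, and transport-interval deltas with an
inclusive threshold (`signed` for a decrease of at least t, `absolute` for
a swing of at least t either way).  A criterion with missing inputs is
false — field practice triggers on observed derangement — and logged.

Delta sign convention: prehospital − in-hospital, so a positive ΔPR is a
pulse-rate *decrease* during transport; "blood-pressure variability" is
|ΔSBP| (absolute mode), with a signed option.

The shipped constants apply the standard physiological criteria at the
prehospital assessment (`CURRENT_1`), the in-hospital assessment
(`CURRENT_2`), or either (`CURRENT_3`), plus the eight-criterion
age-adapted `ALTERNATIVE` guideline.  Static alternative thresholds are
evaluated at *either* assessment (positive if met at either): the
assessment per criterion is not pinned down by the published description,
and "either" is the reading that maximizes sensitivity, consistent with
the guideline's recall-first intent; it is configurable per criterion.
The consciousness criterion accepts AVPU; a GCS ≤ 13 column, when a
dataset carries one, maps onto the same criterion.

## Metrics

Sensitivity (= recall), specificity, precision, accuracy, F1 and F2 are
derived from the 2×2 confusion matrix; undertriage = 1 − sensitivity,
overtriage = 1 − specificity.  Any 0/0 ratio is *undefined* and rendered
blank, never 0 — silent zeros corrupt optimizer objectives on degenerate
folds, so the objective substitutes 0 for an undefined fold score
explicitly, with a logged warning.  Reported rounding is 3 decimals, half
away from zero.  `f_beta_from_counts` computes
(1+β²)·tp / ((1+β²)·tp + β²·fn + fp), the count form that stays defined
when only one of precision/recall is.

## Threshold search

The search space is one inclusion flag per candidate criterion plus its
threshold(s); AVPU-level and AVPU-transition candidates are pure flags.
The objective is the mean held-out F2 over `cv_folds` = 5
outcome-stratified folds (folds fixed by the run seed; the candidate rule
is constant, so cross-validation here estimates out-of-fold score
variability rather than fitting anything).

The optimizer is sequential model-based search: `n_initial` = 30 random
unique parameter vectors, then, per iteration, a random-forest surrogate
(64 trees) is fit to all observed (scaled parameters → objective) pairs
and the next evaluation maximizes expected improvement, with the
mean/spread taken across trees, over a pool of 512 fresh random vectors
plus 128 perturbations of the incumbent; already-evaluated vectors are
never proposed again.  Default budget: 200 evaluations.  Two deliberate
degenerations: `surrogate="random"` gives a seeded random-search ablation
baseline, and a fully discretized space whose size fits inside the budget
is simply enumerated, making the search exact there.  Objective ties are
broken toward fewer included criteria, then the earlier evaluation, so
results are deterministic under a fixed seed.  The chosen rule set is then
evaluated in a single pass on the untouched test split (train/test id
overlap is an error).

The split itself is a deterministic stratified partition (jointly on age
group and each outcome, to keep prevalences comparable across splits):
train size is exactly floor(0.7·n), apportioned per stratum by largest
remainder, shuffled with the seed.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes:

* **Strata.** `elderly_fraction` (default 0.4362) of patients are drawn
  from the age ≥ 65 stratum; ages are truncated normals (77.68 ± 7.92 on
  [65, 105]; 41.74 ± 15.80 on [0, 64]).
* **Vitals.** Prehospital vitals are independent truncated normals inside
  the generation bounds, with the parent (μ, σ) *moment-matched* so the
  truncated distribution reproduces the configured marginal mean (and SD
  where jointly attainable — for SpO2, whose mass piles against the 100 %
  ceiling, the mean is matched exactly and the SD approximately).
  In-hospital values are prehospital + Gaussian drift, clipped to the
  bounds; the drift mean is solved numerically (closed-form clipped-normal
  expectation + Brent root) so the configured in-hospital marginal mean is
  recovered, and the drift SD is √max(sd₂² − sd₁², (0.2·sd₁)²).  Only
  marginal moments are calibrated; the joint prehospital/in-hospital
  pairing is what the delta features need, and additive drift supplies it.
  Defaults reproduce the published stratum marginals (e.g. elderly
  prehospital SBP 143.18 ± 29.39).
* **AVPU.** First-assessment levels are categorical draws from the
  configured stratum frequencies.  The second assessment equals the first
  except for deterioration with probability `transition_noise` (default
  0.03): one step down, with a `transition_au_fraction` (default 0.15)
  chance that an alert patient jumps straight to unresponsive, so the
  A→U criterion occurs at testable frequency.  The configured in-hospital
  AVPU frequencies document the target second-assessment marginal; the
  transition model, not an independent draw, produces it, so improvements
  are not simulated.
* **Injuries.** Each patient draws one injury type (plus a second with
  probability 0.15) from `injury_mix`; typed regions draw an AIS severity
  from `ais_model`, the ISS follows, and untyped ("other") injuries carry
  no AIS codes and no ISS.  Injury severity is independent of the vitals
  processes — subgroup machinery is exercised, but the generator does not
  claim a realistic ISS–outcome correlation.
* **Outcomes.** ICU admission and death are Bernoulli draws from logistic
  models whose features are derangement indicators written in a small
  expression language (`sbp_2<106`, `avpu_2>=V`, `avpu_A_to_U`,
  `|d_sbp|>=60`, `d_pr>=44`, ...), so rule-recoverable signal exists by
  construction and raising a weight provably raises prevalence in the
  deranged subgroup (monotone coupling on shared uniforms).  Death is
  restricted to latently admitted patients (ICU, or ward admission with
  stratum rate 0.292 / 0.140) when `mortality_among_admitted` is on
  (default), mirroring registries whose mortality denominators are
  admitted patients; the admission indicator itself is latent and not a
  schema column.  Default intercepts were calibrated once, by simulation
  at n = 200,000, to the target prevalences (elderly/younger ICU 10.0 % /
  4.7 % marginal; death 10.2 % / 4.2 % of admitted) and frozen.
* **Artifacts.** `inject_artifacts` blanks one required field (probability
  `missing_rate`, default 0.196) or plants one strictly-out-of-range value
  (probability `outlier_rate`, default 0.007) per affected record — the
  two sets disjoint — and returns a manifest of exactly which ids and
  fields were touched, so the filters can be checked for exact agreement.

What passing tests on these cohorts do **not** show: performance on real
registries, where vitals are correlated, missingness is informative,
outcome models are not logistic in threshold indicators, and AVPU can
improve during transport.  The generator validates machinery and
recoverability, not clinical effect sizes.

## Numerical choices and problem sizes

* Moment matching uses `scipy.optimize.least_squares` (fallback: 1-D Brent
  on the mean with σ fixed), cached per parameter tuple; tolerance 1e-6 on
  the matched mean.
* Thresholds in parameter vectors are rounded to 9 decimals to make
  deduplication and tie-breaking exact.
* Rule evaluation is vectorized over the cohort frame; NaN comparisons are
  false by construction.
* Test-suite problem sizes: calibration checks use one 50,000-record
  stratum (3-standard-error band on every configured mean); the
  enumeration-equivalence check uses ten 2,000-record cohorts on a
  209-candidate grid; threshold recovery plants (SBP < 100 OR SpO2 < 92)
  with weight 4.0 on 20,000-record cohorts and requires recovery within
  ±5 mmHg / ±2 points on at least 4 of 5 seeds (the F2 surface on these
  cohorts peaks at the planted thresholds); the surrogate-vs-random
  ablation compares medians over 10 seeds at a budget of 40.

## Known limitations

* The optimizer treats criteria independently in the surrogate's design
  matrix; interactions between included criteria are learned only through
  the forest, which at small budgets can be slow to distinguish plateaus.
* `CohortSpec` carries marginal moments per assessment, not a joint
  covariance; cross-vital correlations (e.g. SBP with PR under shock) are
  absent.
* Mortality denominators: because the admission indicator is latent,
  downstream evaluation of the death outcome uses all records in the
  frame it is given; restricting to admitted patients requires carrying an
  explicit column, which the schema deliberately omits.
* Anatomic and mechanism-of-injury step criteria of full field-triage
  schemes are out of scope; the package models physiological criteria
  only.
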