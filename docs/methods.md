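# Methods

## Scoring systems as data

Each of the seven scores is a packaged YAML definition: ordered half-open
bands `[lo, hi) → points` per physiologic variable, age bands, categorical
points (chronic health, admission type), special rules, and, where one was
published, a logistic mortality transform. The engine interprets the
definitions; no score logic is hard-coded. Validation enforces that every
band table tiles the plausibility range without gap or overlap, that points
are non-negative integers, and that the zero-point band contains the
variable's normal reference value — which is what makes the
missing-as-normal imputation exactly point-neutral. The single exception is
the SAPS II PaO₂/FiO₂ table, a conditional component that only applies to
ventilated patients and whose published bands start at 6 points.

Provenance is recorded per file. The REMS, MEWS, APACHE II and SAPS II
tables and the APACHE II / SAPS II mortality transforms follow the widely
published originals. Three components are documented operationalizations
rather than transcriptions, because the original coefficient tables are not
redistributable here: the PEDS and Seymour cut-offs (banded over exactly
their published variable sets, zero points at normal physiology,
conventional derangement thresholds), and the APACHE III neurologic and
acid-base components (the published eye/motor/verbal and pH×pCO₂ matrices
are collapsed to GCS-total and marginal pH/pCO₂ bands). The REMS
systolic-pressure variant maps the published mean-arterial-pressure bands
onto SBP with a normal band of [90, 150) mmHg, since applying the MAP
cut-points verbatim would score normal blood pressure. Absolute score
values for these components are therefore package-specific; the comparison
machinery (ranking, AUC, calibration) does not depend on the absolute
scale.

Two variable assignments follow the study's own variable map rather than
the score originals: temperature in REMS (APACHE II bands, from which the
REMS bands descend) and potassium in APACHE III (APACHE II bands).

## Windowing and missing data

ICU scores use the most abnormal value of each variable over the first 24
ICU hours; "most abnormal" means the measurement scoring the most points,
with ties broken toward the value farther from the normal reference and
then the earlier timestamp (deterministic, and faithful to the worst-value
intent). ED scores use either the triage measurement (Seymour, as designed
for the pre-hospital setting) or the worst in-ED value (the default for
REMS/MEWS/PEDS, since charted ED care is not a single time point); a
sensitivity mode recomputes all ED scores from the ICU window. The GCS is
taken once per patient from the ICU-admission exam and shared by every
window. The APACHE-family oxygenation component uses the A-a gradient when
FiO₂ ≥ 0.5 and PaO₂ otherwise; the branch variable is chosen after
taking the per-variable worst (highest FiO₂, lowest PaO₂, highest
gradient). Acute renal failure is a caller-supplied flag: it doubles the
APACHE II creatinine points and switches the APACHE III creatinine table.
The APACHE III interaction that waives low respiratory-rate points during
mechanical ventilation is not modelled.

Missing albumin, bilirubin, pH and pCO₂ are imputed at their normal
reference values (zero points); absent chronic-health flags count as
false; MAP is never derived from SBP. Any other missing required variable
makes the score non-computable for that patient, and the completeness
filter applies the study's two-stage accounting: ICU-score completeness
first, then ED-score completeness, with a per-patient, per-variable
exclusion log.

## Inference

The AUC is the tie-corrected Mann–Whitney statistic, computed from
midranks; the ROC polygon is built alongside and its trapezoidal area is
asserted equal to the rank statistic. Standard errors and the covariance of
correlated AUCs use DeLong's structural components
(cov = S₁₀/m + S₀₁/n from the placement values of positives and
negatives); the k-sample equality test is the quadratic form over any
full-rank contrast basis (successive differences by default; the statistic
is basis-invariant), with pairwise z-tests reported against the best-AUC
ICU score, uncorrected for multiplicity (a Bonferroni option exists, off by
default). AUC confidence intervals are Wald intervals truncated to [0, 1];
a logit-transformed variant is available by flag, since the interval method
behind published score CIs is generally unstated.

Calibration recalibrates each score by maximum-likelihood univariate
logistic regression (Newton–Raphson via statsmodels; perfect separation is
flagged as non-convergence), then applies the Hosmer–Lemeshow Ĉ statistic
over ten risk-ordered groups. Grouping uses the quantile-rank rule and
never splits tied predicted values across groups, so integer scores with
few distinct values yield fewer, larger groups; degrees of freedom are
(number of groups) − 2 for model-based probabilities, with a
groups − 0 variant for externally fixed transforms. Groups whose expected
deaths are numerically 0 or equal to the group size raise a degenerate-group
error. Characteristics tables use pooled-variance t tests for continuous
variables and Pearson chi-square without continuity correction for binary
ones, switching to Fisher's exact test when an expected count falls below
5; constant characteristics are reported with a degenerate flag and p = 1.

## Synthetic cohort model

One latent severity factor z ~ N(0, 1) per patient drives everything:

* **Mortality** — logit P(death) = α + βz with β = 1.5 and α solved by
  Gauss–Hermite quadrature so the expected rate equals the target
  (default 57/227 ≈ 25.1%). β = 1.5 was fixed once so that score
  discrimination lands in the 0.70–0.80 AUC range typical of severity
  scores in critically ill cohorts.
* **Windows** — unit-variance window latents u_w = c_w·z + √(1−c_w²)·ε
  with c_icu = √ρ·(1 + d/2) and c_ed = ρ/c_icu, so the between-window
  correlation is exactly ρ (default 0.7, a modelling choice — the real
  within-patient correlation is unknown) while the ICU window carries more
  severity signal when the extra-derangement parameter d > 0 (default
  0.3). The ICU latent additionally gains a magnitude factor (1 + d/2) and
  drift d/2: disease has declared itself by 24 h.
* **Physiology** — value = normal + direction · effect · softplus(u_w) +
  measurement noise, clipped to plausibility bounds. The softplus keeps
  healthier-than-average patients near normal instead of excursing past it.
  Two-tailed variables (temperature, sodium, glucose, pH...) draw a
  per-patient excursion direction from per-variable tail weights, fixed
  across windows. FiO₂ rises with severity and the A-a gradient follows
  the alveolar gas equation from the generated FiO₂/pCO₂/PaO₂, so the
  oxygenation branch is internally consistent. Effect sizes, noise SDs and
  tail weights live in the variable registry; `severity_effect` scales
  them globally (0 severs the physiology–outcome link entirely).
* **Demographics and flags** — service (67% medicine ≡ the MICU subgroup,
  rebalanced to hit the configured MICU fraction exactly), sex, age
  (65 ± 17, coupled to z through a 6 years-per-unit effect so
  non-survivors average ~5 years older), chronic-health flags and
  comorbidities drawn at the study's marginal frequencies, independent of
  z except through age.
* **Missingness** — per-variable, per-window, completely at random, shared
  by both ICU rows. Defaults concentrate missingness where charts have it:
  ED blood gas (~35%), albumin (40%/25%), bilirubin (25%/12%); GCS and
  urine output are never available in the ED. Exclusion-driving rates are
  small, so ~85–90% of a generated cohort survives the completeness
  filter — the generator emulates the *analysis* cohort, whose published
  size is post-exclusion.

What the generator does **not** model: inter-variable physiologic causality
beyond the single factor (no shock patterns, no organ-system clustering),
informative missingness, longitudinal trajectories beyond the two windows,
and flag–outcome associations beyond age. Passing property tests on these
cohorts therefore demonstrates that the machinery is correct and that the
directional contrasts (ICU window ≥ ED window; more derangement ⇒ more
discrimination) emerge from the assumed structure — not that any particular
published AUC value is reproduced, which patient-level data would require.

## Problem sizes and numerics

The test suite checks the engine against hand-tallied fixture patients
(computed from the packaged tables before the engine was built), the AUC
against brute-force pair counting (1000 30-element cases), the DeLong
covariance against a 2000-replicate bootstrap at n = 200, Fisher's test
against hypergeometric enumeration, and Hosmer–Lemeshow against a
hand-computed 20-patient decile table. Null calibration uses 1000
replicates (k = 3 uninformative scores, n = 150) for the equality test's
p-uniformity and 200 replicates (n = 800) for the HL rejection rate;
directional replication averages 50 seeded cohorts at the default n = 227.
Logistic fits converge at gradient norm < 10⁻⁶ (Newton tolerance 10⁻¹⁰);
the ROC-trapezoid/rank-AUC identity is asserted at 10⁻¹⁰. All simulations
take explicit seeds; identical inputs give identical outputs throughout.

## Known limitations

Absolute PEDS/Seymour/APACHE III-neuro point values are package
operationalizations (above), so cross-study comparisons of raw totals for
those scores are not meaningful. The APACHE II mortality transform omits
the diagnostic-category weight (no admission-diagnosis taxonomy is
modelled) and APACHE III has no public transform, so its calibration is
assessed only through recalibration — as the comparison pipeline does for
every score anyway. Units are fixed US clinical conventions; ingest rejects
out-of-range values rather than converting.
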