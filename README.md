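# sevscore

Severity-of-illness scoring and prognostic-model comparison for critically
ill patients admitted to the ICU from the emergency department.

Clinicians and trialists need to know whether the simple scores computable
at ED triage (REMS, MEWS, PEDS, the Seymour pre-hospital score) predict
mortality as well as the data-hungry ICU scores (APACHE II, APACHE III,
SAPS II) that require a full first-24-hour physiology window. `sevscore`
implements all seven scores as data-driven banded point tables, the
windowing and missing-data conventions used to compute them from real
charts, and the statistics used to compare them:

* **Discrimination** — AUC per score, where
  AUC = P(score of a random non-survivor > score of a random survivor),
  estimated by the tie-corrected Mann–Whitney statistic; variances and
  covariances of correlated AUCs by DeLong's placement-value estimator
  V₁₀ᵢ = P̂(neg < posᵢ), V₀₁ⱼ = P̂(pos > negⱼ); the k-sample equality test
  χ² = (LÂ)ᵀ(LSLᵀ)⁻¹(LÂ) with df = k − 1, plus pairwise z-tests.
* **Calibration** — each score is recalibrated by univariate logistic
  regression logit P(death) = β₀ + β₁·score, then assessed with the
  Hosmer–Lemeshow statistic Ĉ = Σ_g (O_g − E_g)² / (E_g(1 − E_g/n_g))
  over ten risk-ordered groups (df = g − 2) and decile calibration plots.
* **Cohort description** — unpaired pooled-variance t tests, Pearson
  chi-square (no continuity correction) and Fisher's exact test.

Because the original patient-level data are not public, the package ships a
**synthetic cohort generator**: a single latent severity factor drives
60-day mortality (calibrated to a 25% rate at n = 227, with a 152-patient
medical-ICU subgroup) and every physiologic variable in two correlated
windows (ED and first-24-h ICU), with realistic missingness. Every pipeline
stage is therefore testable end to end without any data download.

## Worked example

```python
import sevscore as sv

cohort = sv.generate_cohort(sv.CohortSpec(seed=42))        # 227 patients
eligible, log = sv.completeness_filter(cohort)             # two-stage exclusions
disc = sv.run_discrimination(eligible)
print(disc["table"][["score", "window", "auc", "ci_lo", "ci_hi"]].round(3))
```

prints

```
  score        window   auc  ci_lo  ci_hi
   REMS      ed_worst 0.689  0.589  0.788
   MEWS      ed_worst 0.719  0.632  0.807
   PEDS      ed_worst 0.738  0.654  0.823
SEYMOUR     ed_triage 0.722  0.633  0.811
APACHE2 icu_24h_worst 0.783  0.701  0.866
APACHE3 icu_24h_worst 0.768  0.677  0.858
  SAPS2 icu_24h_worst 0.731  0.633  0.829
```

190 of the 227 simulated patients have complete data for all seven scores
(40 of them died by day 60). Each row is a score's AUC with its DeLong 95%
CI, computed on its design window: ED scores on worst-in-ED values, the
Seymour score on triage vitals, ICU scores on worst-in-24-h ICU values. The
ICU scores discriminate best, and `disc["equality"]` carries the overall
DeLong test that all seven AUCs are equal (here χ² = 14.79, df = 6,
p = 0.022). `sv.run_calibration(eligible)` adds the Hosmer–Lemeshow table
(all seven scores pass at p > 0.05 on this cohort), and
`sv.run_full_study(sv.RunConfig(seed=42))` produces the full bundle —
characteristics table, both window modes (including the
ED-scores-on-ICU-data sensitivity analysis), the medical-ICU subgroup, ROC
and decile plot data, and a machine-readable `summary.json`.

The same pipeline runs from the shell:

```
sevscore simulate --n 227 --seed 42 --out cohort/
sevscore score --cohort cohort/ --out scores.csv
sevscore compare --cohort cohort/ --out reports/
sevscore full-study --seed 42 --out study/
```

Estimators compose with scikit-learn: `sv.SeverityScorer(scores=("MEWS",
"APACHE2")).fit(cohort).transform(cohort)` yields a patients × scores
frame, and `sv.ScoreRecalibrator().fit(x, y).predict_proba(x)` is the
logistic recalibration step.

## Layout

```
src/sevscore/definitions/   one YAML per score (banded point tables) + variable registry
src/sevscore/defs.py        definition loading and validation
src/sevscore/cohort.py      cohort containers and CSV I/O
src/sevscore/engine.py      windowing, imputation, scoring
src/sevscore/stats.py       AUC/DeLong/Hosmer-Lemeshow and cohort tests
src/sevscore/simulate.py    synthetic cohort generator
src/sevscore/pipeline.py    study products (tables, plot data, summary JSON)
src/sevscore/cli.py         command-line interface
docs/methods.md             models, assumptions, parameter choices, limitations
```
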