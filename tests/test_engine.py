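"""Scoring engine: windowing, imputation, hand-tallied score oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import sevscore as sv
from sevscore.engine import build_window_snapshot

from conftest import make_record, normal_snapshot


# ---------------------------------------------------------------------------
# all-normal base cases

@pytest.mark.parametrize("name", ["MEWS", "REMS", "PEDS", "SEYMOUR"])
def test_ed_scores_zero_on_normal_physiology(definitions, registry, name):
    rec = make_record(age=40)
    res = sv.score(name, rec, normal_snapshot(registry, window="ed_worst"),
                   definitions, registry)
    assert res.value == 0
    assert not res.excluded


def test_apache2_zero_on_young_normal_nonoperative(definitions, registry):
    rec = make_record(age=30)
    res = sv.score("APACHE2", rec, normal_snapshot(registry),
                   definitions, registry)
    assert res.value == 0


def test_saps2_on_normal_scores_only_admission_type(definitions, registry):
    # a 30-year-old medical admission with normal physiology: 6 points
    rec = make_record(age=30)
    res = sv.score("SAPS2", rec, normal_snapshot(registry),
                   definitions, registry)
    assert res.value == 6


# ---------------------------------------------------------------------------
# hand-tallied fixture patients (tallies computed from the packaged band
# tables before the engine was built)

def test_apache2_matches_hand_tally(definitions, registry):
    rec = make_record(age=68, chronic_flags=frozenset({"immunosuppressed"}))
    snap = normal_snapshot(
        registry, temperature=39.5, map=62, heart_rate=122,
        respiratory_rate=33, fio2=0.6, aa_gradient=310, ph=7.28, sodium=152,
        potassium=5.7, creatinine=2.2, hematocrit=28, wbc=17, gcs_total=10)
    snap.acute_renal_failure = True
    res = sv.score("APACHE2", rec, snap, definitions, registry)
    # physiology 28 (incl. doubled creatinine 6) + age 5 + chronic health 5
    assert res.value == 38
    assert res.predicted_mortality == pytest.approx(
        1 / (1 + np.exp(-(-3.517 + 0.146 * 38))), abs=1e-12)


def test_apache3_matches_hand_tally(definitions, registry):
    rec = make_record(
        age=72, chronic_flags=frozenset({"hepatic_failure_or_cirrhosis"}))
    snap = normal_snapshot(
        registry, heart_rate=142, map=55, temperature=35.5,
        respiratory_rate=28, fio2=0.4, pao2=62, hematocrit=38, wbc=22,
        creatinine=1.2, urine_output_24h=800, bun=45, sodium=133,
        potassium=4.2, albumin=2.2, bilirubin=3.5, glucose=250, gcs_total=9,
        ph=7.22, pco2=60)
    res = sv.score("APACHE3", rec, snap, definitions, registry)
    # physiology 107 + age 16 + chronic (hepatic failure) 16
    assert res.value == 139


def test_saps2_matches_hand_tally(definitions, registry):
    rec = make_record(age=76, chronic_flags=frozenset(
        {"metastatic_cancer", "hematologic_malignancy"}))
    snap = normal_snapshot(
        registry, heart_rate=45, sbp=88, temperature=38.2, pao2=90, fio2=0.5,
        urine_output_24h=650, bun=90, wbc=0.8, potassium=2.7, sodium=128,
        bicarbonate=17, gcs_total=12)
    snap.ventilated = True
    snap.values.pop("bilirubin")  # imputed as normal -> 0 points
    res = sv.score("SAPS2", rec, snap, definitions, registry)
    # physiology 53 (incl. P/F 180 -> 9) + age 16 + chronic max 10 + medical 6
    assert res.value == 85
    assert res.imputed_fields == {"bilirubin"}
    logit = -7.7631 + 0.0737 * 85 + 0.9971 * np.log(86)
    assert res.predicted_mortality == pytest.approx(
        1 / (1 + np.exp(-logit)), abs=1e-12)


@pytest.mark.parametrize("name,overrides,age,expected", [
    ("REMS", dict(heart_rate=115, respiratory_rate=8, sbp=85,
                  temperature=36.5, spo2=88, gcs_total=12), 80, 14),
    ("MEWS", dict(heart_rate=105, respiratory_rate=22, sbp=95,
                  temperature=34.5, gcs_total=13), 55, 7),
    ("SEYMOUR", dict(sbp=95, respiratory_rate=25, heart_rate=120, spo2=92,
                     gcs_total=14), 70, 8),
])
def test_ed_scores_match_hand_tally(definitions, registry, name, overrides,
                                    age, expected):
    rec = make_record(age=age)
    res = sv.score(name, rec, normal_snapshot(registry, window="ed_worst",
                                              **overrides),
                   definitions, registry)
    assert res.value == expected


def test_peds_matches_hand_tally(definitions, registry):
    rec = make_record(age=50, chronic_flags=frozenset({"metastatic_cancer"}))
    snap = normal_snapshot(registry, sbp=85, gcs_total=13, glucose=200,
                           bicarbonate=18, wbc=15)
    res = sv.score("PEDS", rec, snap, definitions, registry)
    assert res.value == 9


# ---------------------------------------------------------------------------
# missing-data policy

def test_missing_normal_policy_imputes_only_policy_variables(definitions,
                                                             registry):
    snap = pd.DataFrame({"albumin": [np.nan, 3.0], "sodium": [np.nan, 140.0],
                         "ph": [7.2, np.nan]}, index=["a", "b"])
    out, imputed = sv.apply_missing_normal_policy(
        snap, definitions["APACHE3"], registry)
    assert out.loc["a", "albumin"] == registry["albumin"].normal
    assert out.loc["b", "albumin"] == 3.0
    assert np.isnan(out.loc["a", "sodium"])  # not in the policy list
    assert out.loc["a", "ph"] == 7.2
    assert out.loc["b", "ph"] == registry["ph"].normal
    assert imputed.loc["a", "albumin"] and not imputed.loc["b", "albumin"]


def test_imputation_is_point_neutral(definitions, registry):
    """Imputing a policy variable as normal contributes exactly 0 points."""
    rec = make_record(age=30)
    full = sv.score("APACHE3", rec, normal_snapshot(registry),
                    definitions, registry)
    snap = normal_snapshot(registry)
    for var in ("albumin", "bilirubin", "ph", "pco2"):
        snap.values.pop(var)
    imputed = sv.score("APACHE3", rec, snap, definitions, registry)
    assert imputed.value == full.value
    assert imputed.imputed_fields == {"albumin", "bilirubin", "ph", "pco2"}


def test_missing_required_variable_excludes_with_reason(definitions, registry):
    snap = normal_snapshot(registry)
    snap.values.pop("heart_rate")
    res = sv.score("APACHE2", make_record(), snap, definitions, registry)
    assert res.excluded and res.value is None
    assert "heart_rate" in res.reason


def test_unknown_score_name_rejected(definitions, registry):
    with pytest.raises(KeyError):
        sv.score("APACHE4", make_record(), normal_snapshot(registry),
                 definitions, registry)


# ---------------------------------------------------------------------------
# worst-window aggregation

def _measurements(registry, rows):
    frames = []
    for ts, overrides in rows:
        vals = {name: spec.normal for name, spec in registry.items()}
        vals.update(overrides)
        frames.append({"patient_id": "p1", "window": "icu_24h",
                       "timestamp": ts, **vals,
                       "acute_renal_failure": 0.0, "ventilated": 0.0})
    return pd.DataFrame(frames)


def test_worst_window_single_measurement_identity(definitions, registry):
    m = _measurements(registry, [(1.0, {"heart_rate": 97.0})])
    out = sv.aggregate_worst_window(m, definitions["APACHE2"], registry)
    assert out.loc["p1", "heart_rate"] == 97.0


def test_worst_window_selects_max_points(definitions, registry):
    m = _measurements(registry, [(1.0, {"heart_rate": 70.0}),
                                 (2.0, {"heart_rate": 145.0})])
    out = sv.aggregate_worst_window(m, definitions["APACHE2"], registry)
    assert out.loc["p1", "heart_rate"] == 145.0


def test_worst_window_tie_prefers_farther_from_normal(definitions, registry):
    # 112 and 120 both score 2 MEWS heart-rate points; 120 is farther from 75
    m = _measurements(registry, [(1.0, {"heart_rate": 112.0}),
                                 (2.0, {"heart_rate": 120.0})])
    out = sv.aggregate_worst_window(m, definitions["MEWS"], registry)
    assert out.loc["p1", "heart_rate"] == 120.0


def test_worst_window_remaining_tie_prefers_earlier(definitions, registry):
    m = _measurements(registry, [(5.0, {"heart_rate": 115.0}),
                                 (2.0, {"heart_rate": 115.0})])
    out = sv.aggregate_worst_window(m, definitions["MEWS"], registry)
    assert out.loc["p1", "heart_rate"] == 115.0


def test_worst_window_empty_errors(definitions, registry):
    with pytest.raises(ValueError, match="empty"):
        sv.aggregate_worst_window(pd.DataFrame(columns=["patient_id"]),
                                  definitions["APACHE2"], registry)


def test_window_consistency_never_scores_below_any_measurement(
        definitions, registry):
    """Worst-window points per variable >= points of each measurement."""
    rng = np.random.default_rng(7)
    d = definitions["APACHE2"]
    rows = []
    for ts in (1.0, 5.0, 9.0):
        overrides = {
            "heart_rate": float(rng.uniform(20, 220)),
            "temperature": float(rng.uniform(28, 43)),
            "sodium": float(rng.uniform(110, 180)),
        }
        rows.append((ts, overrides))
    m = _measurements(registry, rows)
    out = sv.aggregate_worst_window(m, d, registry)
    for var in ("heart_rate", "temperature", "sodium"):
        worst_pts = d.band_tables[var].lookup(out[var].to_numpy())[0]
        each = d.band_tables[var].lookup(m[var].to_numpy())
        assert worst_pts >= each.max()


def test_gcs_shared_from_icu_admission_exam(definitions, registry):
    """ED-window snapshots take the GCS from the earliest ICU measurement."""
    rows = []
    for win, ts, gcs in (("ed", 0.0, np.nan), ("icu_24h", 1.0, 9.0),
                         ("icu_24h", 13.0, 14.0)):
        vals = {name: spec.normal for name, spec in registry.items()}
        vals["gcs_total"] = gcs
        rows.append({"patient_id": "p1", "window": win, "timestamp": ts,
                     **vals, "acute_renal_failure": 0.0, "ventilated": 0.0})
    patients = pd.DataFrame({
        "age": [50], "sex": ["male"], "admitting_service": ["medicine"],
        "micu": [True], "admission_category": ["nonoperative"],
        "medical_admission": [True], "unscheduled_surgery": [False],
        **{f"flag_{f}": [False] for f in sv.cohort.CHRONIC_FLAGS},
        **{c: [False] for c in sv.cohort.COMORBIDITIES},
        "died_60d": [False], "died_inhospital": [False],
    }, index=pd.Index(["p1"], name="patient_id"))
    cohort = sv.Cohort(patients, pd.DataFrame(rows))
    for window in ("ed_triage", "ed_worst", "icu_24h_worst"):
        snap = build_window_snapshot(cohort, window, definitions["MEWS"],
                                     registry)
        assert snap.loc["p1", "gcs_total"] == 9.0, window


# ---------------------------------------------------------------------------
# invariants

def test_determinism_identical_inputs_identical_results(eligible_cohort,
                                                        definitions, registry):
    a = sv.score_cohort(eligible_cohort, definitions=definitions,
                        registry=registry)
    b = sv.score_cohort(eligible_cohort, definitions=definitions,
                        registry=registry)
    pd.testing.assert_frame_equal(a, b)


@pytest.mark.parametrize("name,var,worse", [
    ("MEWS", "heart_rate", [75, 105, 115, 135]),
    ("APACHE2", "sodium", [140, 152, 157, 165, 185]),
    ("SAPS2", "gcs_total", [15, 13, 10, 8, 5]),
    ("APACHE3", "creatinine", [0.9, 1.6, 2.5]),
])
def test_monotone_derangement_never_decreases_score(definitions, registry,
                                                    name, var, worse):
    rec = make_record(age=40)
    prev = -1
    for v in worse:
        snap = normal_snapshot(registry, **{var: v})
        val = sv.score(name, rec, snap, definitions, registry).value
        assert val >= prev
        prev = val


def test_value_bounded_by_max_attainable(definitions, registry):
    rec = make_record(age=95, chronic_flags=frozenset(sv.cohort.CHRONIC_FLAGS),
                      admission_category="emergency_postoperative",
                      medical_admission=False, unscheduled_surgery=True)
    snap = normal_snapshot(
        registry, temperature=25, heart_rate=250, respiratory_rate=70,
        sbp=30, map=25, spo2=40, gcs_total=3, fio2=1.0, aa_gradient=650,
        pao2=25, ph=6.6, pco2=150, sodium=195, potassium=9.5, creatinine=20,
        bun=200, bicarbonate=3, glucose=1400, bilirubin=50, albumin=0.9,
        hematocrit=70, wbc=150, urine_output_24h=0)
    snap.acute_renal_failure = True
    snap.ventilated = True
    for name, d in definitions.items():
        res = sv.score(name, rec, snap, definitions, registry)
        assert 0 <= res.value <= d.max_score, name


# ---------------------------------------------------------------------------
# predicted mortality

def test_predicted_mortality_monotone_in_score(definitions):
    rec = make_record()
    probs = [sv.predicted_mortality(
        sv.ScoreResult("APACHE2", s, "icu_24h_worst"), rec, definitions)
        for s in range(0, 72, 3)]
    assert np.all(np.diff(probs) >= 0)
    assert all(0 < p < 1 for p in probs)


def test_predicted_mortality_half_at_logit_zero_crossing(definitions):
    # APACHE II: -3.517 + 0.146 s = 0 at s = 24.089...
    rec = make_record()
    s0 = 3.517 / 0.146
    p = sv.predicted_mortality(sv.ScoreResult("APACHE2", s0, "icu_24h_worst"),
                               rec, definitions)
    assert p == pytest.approx(0.5, abs=1e-12)


def test_predicted_mortality_requires_transform_or_recalibration(definitions):
    rec = make_record()
    res = sv.ScoreResult("MEWS", 4, "ed_worst")
    with pytest.raises(ValueError, match="recalibration"):
        sv.predicted_mortality(res, rec, definitions)
    p = sv.predicted_mortality(res, rec, definitions,
                               recalibration=(-3.0, 0.5))
    assert p == pytest.approx(1 / (1 + np.exp(-(-3.0 + 0.5 * 4))))


def test_apache2_emergency_surgery_term(definitions):
    rec_med = make_record()
    rec_es = make_record(admission_category="emergency_postoperative",
                         medical_admission=False, unscheduled_surgery=True)
    res = sv.ScoreResult("APACHE2", 20, "icu_24h_worst")
    p_med = sv.predicted_mortality(res, rec_med, definitions)
    p_es = sv.predicted_mortality(res, rec_es, definitions)
    assert p_es > p_med


# ---------------------------------------------------------------------------
# completeness filter

def test_completeness_filter_identity_on_complete_cohort(eligible_cohort,
                                                         definitions):
    again, log = sv.completeness_filter(eligible_cohort, definitions)
    assert again.n_patients == eligible_cohort.n_patients
    assert log.empty


def test_completeness_filter_two_stage_accounting(default_cohort, definitions):
    eligible, log = sv.completeness_filter(default_cohort, definitions)
    assert eligible.n_patients < default_cohort.n_patients
    assert set(log["stage"]) <= {"icu", "ed"}
    # ICU-stage exclusions are charged to ICU scores only
    icu_rows = log[log["stage"] == "icu"]
    assert set(icu_rows["score"]) <= set(sv.ICU_SCORES)
    # excluded patients do not reappear in the eligible cohort
    assert not set(log["patient_id"]) & set(eligible.patients.index)


def test_patient_missing_only_albumin_is_retained(default_cohort, definitions,
                                                  registry):
    # albumin is imputable: a patient complete except albumin must survive
    cohort = default_cohort
    values, meta = sv.score_cohort(cohort, ["APACHE3"], definitions=definitions,
                                   registry=registry, with_meta=True)
    imput = meta["APACHE3"]["imputed"]
    complete_with_imputed_albumin = values["APACHE3"].notna() & imput["albumin"]
    assert complete_with_imputed_albumin.any()


# ---------------------------------------------------------------------------
# sklearn estimator surface

def test_severity_scorer_estimator_contract(eligible_cohort):
    scorer = sv.SeverityScorer(scores=("MEWS", "APACHE2"))
    assert clone(scorer).get_params()["scores"] == ("MEWS", "APACHE2")
    out = scorer.fit(eligible_cohort).transform(eligible_cohort)
    assert list(out.columns) == ["MEWS", "APACHE2"]
    assert hasattr(scorer, "definitions_")
    forced = sv.SeverityScorer(scores=("MEWS",), window="icu_24h_worst")
    out_icu = forced.fit(eligible_cohort).transform(eligible_cohort)
    assert not out_icu["MEWS"].equals(out["MEWS"])
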