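"""Severity-score computation engine.

Applies a :class:`~sevscore.defs.ScoreDefinition` to patient records plus
physiology, with the study's windowing and missing-data conventions:

* ICU scores use the most abnormal ("worst") value of each variable over the
  first 24 ICU hours; ED scores use either the triage measurement
  (``ed_triage``) or the worst ED measurement (``ed_worst``).
* The GCS is taken once per patient from the ICU-admission exam and shared
  by every window.
* Missing albumin, bilirubin, pH and pCO2 are imputed as normal (zero
  points); absent chronic-health flags count as false. Any other missing
  required variable makes the score non-computable for that patient.
* Worst-value ties (equal points) keep the value farther from the normal
  reference; remaining ties keep the earlier timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import Cohort, PatientRecord, PhysiologySnapshot
from .defs import (ED_SCORES, ICU_SCORES, SCORE_NAMES, ScoreDefinition,
                   VariableSpec, load_score_definitions, load_variable_registry)

__all__ = [
    "ScoreResult", "SeverityScorer", "apply_missing_normal_policy",
    "aggregate_worst_window", "build_window_snapshot", "score",
    "score_cohort", "completeness_filter", "predicted_mortality",
]


@dataclass
class ScoreResult:
    """Outcome of computing one score for one patient."""

    score_name: str
    value: float | None
    window_used: str
    predicted_mortality: float | None = None
    imputed_fields: frozenset = frozenset()
    excluded: bool = False
    reason: str | None = None


def _flag_any(series: pd.Series) -> pd.Series:
    """Group-reduce a 0/1/NaN flag column with 'any true, else false'."""
    return series.fillna(0).astype(float).max()


def apply_missing_normal_policy(
    snapshot: pd.DataFrame,
    definition: ScoreDefinition,
    registry: Mapping[str, VariableSpec],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute the definition's policy variables as normal where missing.

    Returns the imputed snapshot and a boolean frame (same index) marking
    which fields were imputed for which patient. Variables outside the
    policy list are left missing.
    """
    out = snapshot.copy()
    imputed = pd.DataFrame(False, index=snapshot.index,
                           columns=sorted(definition.impute_normal_variables))
    for var in definition.impute_normal_variables:
        if var not in out.columns:
            out[var] = np.nan
        out[var] = out[var].astype(float)
        mask = out[var].isna()
        out.loc[mask, var] = registry[var].normal
        imputed[var] = mask.to_numpy()
    return out, imputed


def _worst_per_patient(rows: pd.DataFrame, var: str, table,
                       normal: float) -> pd.Series:
    """Most-abnormal value of ``var`` per patient under a band table."""
    sub = rows.loc[rows[var].notna(), ["patient_id", var]].copy()
    if sub.empty:
        return pd.Series(dtype=float)
    sub["_pts"] = table.lookup(sub[var].to_numpy())
    sub["_dist"] = (sub[var] - normal).abs()
    sub["_ts"] = rows.loc[sub.index, "timestamp"] if "timestamp" in rows else 0.0
    sub = sub.sort_values(["_pts", "_dist", "_ts"],
                          ascending=[False, False, True], kind="mergesort")
    return sub.drop_duplicates("patient_id").set_index("patient_id")[var]


def aggregate_worst_window(
    measurements: pd.DataFrame,
    definition: ScoreDefinition,
    registry: Mapping[str, VariableSpec],
    window_label: str = "icu_24h_worst",
) -> pd.DataFrame:
    """Collapse timestamped measurements to one worst-value row per patient.

    For each banded variable the measurement scoring the most points is kept
    (ties: farther from normal, then earlier). FiO2 keeps its maximum,
    PaO2/FiO2 its minimum, and the operational flags are true if true in any
    measurement.
    """
    if measurements.empty:
        raise ValueError("empty measurement window")
    pids = pd.Index(measurements["patient_id"].unique(), name="patient_id")
    out = pd.DataFrame(index=pids)
    out["window"] = window_label
    for var, table in definition.band_tables.items():
        if var in ("creatinine_arf", "pf_ratio"):
            continue
        if var not in measurements.columns:
            out[var] = np.nan
            continue
        normal = registry[var].normal
        out[var] = _worst_per_patient(measurements, var, table, normal)
    if definition.special.get("oxygenation"):
        if "fio2" in measurements.columns:
            out["fio2"] = measurements.groupby("patient_id")["fio2"].max()
        else:
            out["fio2"] = np.nan
    if definition.special.get("pf_ratio_if_ventilated"):
        if {"pao2", "fio2"} <= set(measurements.columns):
            have = measurements["pao2"].notna() & measurements["fio2"].notna()
            sub = measurements.loc[have]
            ratio = sub["pao2"] / sub["fio2"]
            out["pf_ratio"] = ratio.groupby(sub["patient_id"]).min()
        else:
            out["pf_ratio"] = np.nan
    for flag in ("acute_renal_failure", "ventilated"):
        if flag in measurements.columns:
            out[flag] = measurements.groupby("patient_id")[flag].apply(_flag_any)
        else:
            out[flag] = np.nan
    return out


def _triage_snapshot(measurements: pd.DataFrame,
                     definition: ScoreDefinition) -> pd.DataFrame:
    first = (measurements.sort_values("timestamp", kind="mergesort")
             .drop_duplicates("patient_id").set_index("patient_id"))
    out = first.drop(columns=["window", "timestamp"], errors="ignore").copy()
    out.insert(0, "window", "ed_triage")
    if definition.special.get("pf_ratio_if_ventilated"):
        if {"pao2", "fio2"} <= set(out.columns):
            out["pf_ratio"] = out["pao2"] / out["fio2"]
        else:
            out["pf_ratio"] = np.nan
    return out


def build_window_snapshot(
    cohort: Cohort,
    window: str,
    definition: ScoreDefinition,
    registry: Mapping[str, VariableSpec],
) -> pd.DataFrame:
    """One scoring-ready row per patient for the requested window.

    ``window`` is one of ``ed_triage``, ``ed_worst``, ``icu_24h_worst``.
    The GCS total is overridden with the earliest ICU measurement (the
    ICU-admission exam) whenever one exists, for every window.
    """
    phys = cohort.physiology
    if window == "ed_triage":
        rows = phys[phys["window"] == "ed"]
        snap = _triage_snapshot(rows, definition)
    elif window == "ed_worst":
        rows = phys[phys["window"] == "ed"]
        if rows.empty:
            raise ValueError("no ED measurements in cohort")
        snap = aggregate_worst_window(rows, definition, registry, "ed_worst")
    elif window == "icu_24h_worst":
        rows = phys[phys["window"] == "icu_24h"]
        if rows.empty:
            raise ValueError("no ICU measurements in cohort")
        snap = aggregate_worst_window(rows, definition, registry, "icu_24h_worst")
    else:
        raise ValueError(f"unknown window {window!r}")
    icu = phys[phys["window"] == "icu_24h"]
    if not icu.empty and "gcs_total" in icu.columns:
        adm = (icu[icu["gcs_total"].notna()]
               .sort_values("timestamp", kind="mergesort")
               .drop_duplicates("patient_id").set_index("patient_id")["gcs_total"])
        shared = adm.reindex(snap.index)
        if "gcs_total" not in snap.columns:
            snap["gcs_total"] = np.nan
        snap["gcs_total"] = shared.fillna(snap["gcs_total"])
    return snap.reindex(cohort.patients.index)


_ADMISSION_TYPE = {
    "nonoperative": "medical",
    "emergency_postoperative": "unscheduled_surgical",
    "elective_postoperative": "scheduled_surgical",
}


def _score_frame(
    definition: ScoreDefinition,
    patients: pd.DataFrame,
    snapshot: pd.DataFrame,
    registry: Mapping[str, VariableSpec],
) -> tuple[pd.Series, dict[str, list[str]], pd.DataFrame]:
    """Vectorised scoring of a prepared snapshot.

    Returns (values with NaN where non-computable, missing-variable map,
    imputed-field frame).
    """
    snap, imputed = apply_missing_normal_policy(snapshot, definition, registry)
    idx = snap.index
    pts = pd.Series(0.0, index=idx)
    missing: dict[str, list[str]] = {}

    def note_missing(mask: pd.Series, varname: str) -> None:
        for pid in idx[mask.to_numpy(dtype=bool)]:
            missing.setdefault(pid, []).append(varname)

    special = definition.special
    skip = {"creatinine_arf", "pf_ratio"}
    if special.get("oxygenation"):
        skip |= {"pao2", "aa_gradient"}
    if special.get("creatinine_arf"):
        skip |= {"creatinine"}
    for var in definition.required_variables:
        col = snap[var] if var in snap.columns else pd.Series(np.nan, index=idx)
        note_missing(col.isna(), var)
    for var, table in definition.band_tables.items():
        if var in skip:
            continue
        col = snap[var] if var in snap.columns else pd.Series(np.nan, index=idx)
        pts += table.lookup(col.to_numpy())

    if special.get("oxygenation"):
        thr = float(special.get("oxygenation_fio2_threshold", 0.5))
        fio2 = snap.get("fio2", pd.Series(np.nan, index=idx))
        pao2 = snap.get("pao2", pd.Series(np.nan, index=idx))
        aag = snap.get("aa_gradient", pd.Series(np.nan, index=idx))
        use_aa = fio2 >= thr
        note_missing(fio2.isna(), "fio2")
        note_missing(use_aa & aag.isna(), "aa_gradient")
        note_missing(fio2.notna() & ~use_aa & pao2.isna(), "pao2")
        ox = np.where(use_aa,
                      definition.band_tables["aa_gradient"].lookup(aag.to_numpy()),
                      definition.band_tables["pao2"].lookup(pao2.to_numpy()))
        pts += ox

    arf_mode = special.get("creatinine_arf")
    if arf_mode:
        cr = snap.get("creatinine", pd.Series(np.nan, index=idx))
        arf = snap.get("acute_renal_failure",
                       pd.Series(np.nan, index=idx)).fillna(0).astype(bool)
        base = definition.band_tables["creatinine"].lookup(cr.to_numpy())
        if arf_mode == "double":
            pts += np.where(arf, 2 * base, base)
        elif arf_mode == "switch":
            alt = definition.band_tables["creatinine_arf"].lookup(cr.to_numpy())
            pts += np.where(arf, alt, base)
        else:
            raise ValueError(f"unknown creatinine_arf mode {arf_mode!r}")

    if special.get("pf_ratio_if_ventilated"):
        vent = snap.get("ventilated",
                        pd.Series(np.nan, index=idx)).fillna(0).astype(bool)
        ratio = snap.get("pf_ratio", pd.Series(np.nan, index=idx))
        note_missing(vent & ratio.isna(), "pao2/fio2")
        ok = vent & ratio.notna()
        pts += np.where(ok, definition.band_tables["pf_ratio"].lookup(ratio.to_numpy()), 0)

    if definition.age_bands is not None:
        pts += definition.age_bands.lookup(patients["age"].to_numpy())

    category = patients["admission_category"]
    if definition.chronic_health:
        qual = pd.Series(False, index=idx)
        for f in definition.chronic_health["qualifying_flags"]:
            qual |= patients[f"flag_{f}"].astype(bool)
        cat_pts = category.map(
            definition.chronic_health["points_by_admission_category"]).fillna(0)
        pts += np.where(qual, cat_pts, 0)

    if definition.chronic_flag_points:
        flag_pts = np.zeros((len(idx), len(definition.chronic_flag_points)))
        for j, (f, p) in enumerate(definition.chronic_flag_points.items()):
            flag_pts[:, j] = patients[f"flag_{f}"].astype(bool).to_numpy() * p
        agg = (flag_pts.max(axis=1) if definition.chronic_flag_mode == "max"
               else flag_pts.sum(axis=1))
        if definition.chronic_flag_excluded_categories:
            waived = category.isin(definition.chronic_flag_excluded_categories)
            agg = np.where(waived.to_numpy(), 0, agg)
        pts += agg

    if definition.admission_type_points:
        pts += category.map(_ADMISSION_TYPE).map(
            definition.admission_type_points).fillna(0).to_numpy()

    values = pts.astype(float)
    values[values.index.isin(missing)] = np.nan
    return values, missing, imputed


def score_cohort(
    cohort: Cohort,
    scores: Sequence[str] | str = "all",
    window: str | Mapping[str, str] | None = None,
    definitions: Mapping[str, ScoreDefinition] | None = None,
    registry: Mapping[str, VariableSpec] | None = None,
    with_meta: bool = False,
):
    """Compute the requested scores for every patient in a cohort.

    Parameters
    ----------
    window
        ``None`` uses each definition's default window (ED scores on ED
        data, Seymour on triage vitals, ICU scores on worst-in-24 h ICU
        data); a single window name forces it for every score (the
        ED-scores-on-ICU-data sensitivity analysis uses
        ``"icu_24h_worst"``); a mapping assigns windows per score.

    Returns
    -------
    DataFrame of score values indexed by patient_id (NaN = non-computable);
    with ``with_meta=True`` also a dict with per-score missing-variable maps,
    imputed-field frames and the window actually used.
    """
    definitions = definitions or load_score_definitions()
    registry = registry or load_variable_registry()
    names = list(SCORE_NAMES) if scores == "all" else list(scores)
    out = pd.DataFrame(index=cohort.patients.index)
    meta: dict[str, dict] = {}
    for name in names:
        if name not in definitions:
            raise KeyError(f"unknown score {name!r}")
        d = definitions[name]
        if window is None:
            win = d.default_window
        elif isinstance(window, str):
            win = window
        else:
            win = window.get(name, d.default_window)
        snap = build_window_snapshot(cohort, win, d, registry)
        values, missing, imputed = _score_frame(d, cohort.patients, snap, registry)
        out[name] = values
        meta[name] = {"window": win, "missing": missing, "imputed": imputed}
    return (out, meta) if with_meta else out


def score(
    name: str,
    record: PatientRecord,
    snapshot: PhysiologySnapshot,
    definitions: Mapping[str, ScoreDefinition] | None = None,
    registry: Mapping[str, VariableSpec] | None = None,
) -> ScoreResult:
    """Compute one score for one patient from a prepared snapshot.

    The snapshot is taken as already windowed (its ``window`` field records
    provenance); the missing-as-normal policy is applied here.
    """
    definitions = definitions or load_score_definitions()
    registry = registry or load_variable_registry()
    if name not in definitions:
        raise KeyError(f"unknown score {name!r}")
    d = definitions[name]
    row = {var: snapshot.get(var) for var in registry}
    row["acute_renal_failure"] = (np.nan if snapshot.acute_renal_failure is None
                                  else float(snapshot.acute_renal_failure))
    row["ventilated"] = (np.nan if snapshot.ventilated is None
                         else float(snapshot.ventilated))
    if d.special.get("pf_ratio_if_ventilated"):
        row["pf_ratio"] = row["pao2"] / row["fio2"]
    snap = pd.DataFrame([row], index=pd.Index([record.patient_id],
                                              name="patient_id"))
    pats = pd.DataFrame(
        {
            "age": [record.age],
            "admission_category": [record.admission_category],
            **{f"flag_{f}": [f in record.chronic_flags]
               for f in sorted({*_all_flags(definitions)})},
        },
        index=snap.index,
    )
    values, missing, imputed = _score_frame(d, pats, snap, registry)
    pid = record.patient_id
    if pid in missing:
        return ScoreResult(name, None, snapshot.window, excluded=True,
                           reason=f"missing {sorted(set(missing[pid]))}")
    value = float(values.iloc[0])
    if value.is_integer():
        value = int(value)
    imp = frozenset(c for c in imputed.columns if imputed.iloc[0][c])
    result = ScoreResult(name, value, snapshot.window, imputed_fields=imp)
    if d.has_mortality_transform:
        result.predicted_mortality = predicted_mortality(result, record,
                                                         definitions=definitions)
    return result


def _all_flags(definitions: Mapping[str, ScoreDefinition]) -> set[str]:
    flags: set[str] = set()
    for d in definitions.values():
        flags |= set(d.chronic_flag_points)
        if d.chronic_health:
            flags |= set(d.chronic_health["qualifying_flags"])
    return flags


def predicted_mortality(
    result: ScoreResult,
    record: PatientRecord,
    definitions: Mapping[str, ScoreDefinition] | None = None,
    recalibration: tuple[float, float] | None = None,
) -> float:
    """Predicted death probability for a computed score.

    Uses the definition's published logistic transform (APACHE II, SAPS II),
    or a supplied ``(intercept, slope)`` recalibration for any score.
    """
    if result.value is None:
        raise ValueError("score was not computable")
    s = float(result.value)
    if recalibration is not None:
        b0, b1 = recalibration
        logit = b0 + b1 * s
    else:
        definitions = definitions or load_score_definitions()
        d = definitions[result.score_name]
        if not d.has_mortality_transform:
            raise ValueError(
                f"{result.score_name} has no published mortality transform; "
                "supply a fitted recalibration")
        t = d.mortality_transform
        logit = t["intercept"] + t["slope"] * s
        if "log_slope" in t:
            logit += t["log_slope"] * np.log(s + 1.0)
        if "emergency_surgery" in t and record is not None:
            if record.admission_category == "emergency_postoperative":
                logit += t["emergency_surgery"]
    return float(1.0 / (1.0 + np.exp(-logit)))


def completeness_filter(
    cohort: Cohort,
    definitions: Mapping[str, ScoreDefinition] | None = None,
    registry: Mapping[str, VariableSpec] | None = None,
    icu_scores: Sequence[str] = ICU_SCORES,
    ed_scores: Sequence[str] = ED_SCORES,
) -> tuple[Cohort, pd.DataFrame]:
    """Two-stage complete-case filter mirroring the study's accounting.

    Stage 1 drops patients for whom any ICU score is non-computable on the
    ICU window; stage 2 drops, from the remainder, patients for whom any ED
    score is non-computable on its default window. Returns the eligible
    cohort and a log with one row per (patient, score, missing variable).
    """
    definitions = definitions or load_score_definitions()
    registry = registry or load_variable_registry()
    log_rows = []
    excluded: set[str] = set()
    for stage, names in (("icu", list(icu_scores)), ("ed", list(ed_scores))):
        sub_ids = [p for p in cohort.patients.index if p not in excluded]
        sub = cohort.subset(sub_ids)
        _, meta = score_cohort(sub, names, definitions=definitions,
                               registry=registry, with_meta=True)
        for name in names:
            for pid, vars_ in meta[name]["missing"].items():
                excluded.add(pid)
                for v in sorted(set(vars_)):
                    log_rows.append({"stage": stage, "patient_id": pid,
                                     "score": name, "missing_variable": v})
    keep = [p for p in cohort.patients.index if p not in excluded]
    log = pd.DataFrame(log_rows,
                       columns=["stage", "patient_id", "score", "missing_variable"])
    return cohort.subset(keep), log


class SeverityScorer(BaseEstimator, TransformerMixin):
    """Transformer computing severity scores from a :class:`Cohort`.

    ``fit`` loads and validates the score definitions; ``transform`` maps a
    cohort to a patients x scores DataFrame of score values (NaN where a
    score is not computable for a patient).

    Parameters
    ----------
    scores : "all" or sequence of score names
    window : None, window name, or mapping score->window
        See :func:`score_cohort`.
    definitions_path : optional directory of user-supplied definition YAMLs.
    """

    def __init__(self, scores="all", window=None, definitions_path=None):
        self.scores = scores
        self.window = window
        self.definitions_path = definitions_path

    def fit(self, X: Cohort | None = None, y=None) -> "SeverityScorer":
        self.definitions_ = load_score_definitions(self.definitions_path)
        self.registry_ = load_variable_registry(
            None if self.definitions_path is None
            else f"{self.definitions_path}/variables.yaml")
        self.score_names_ = (list(SCORE_NAMES) if self.scores == "all"
                             else list(self.scores))
        return self

    def transform(self, X: Cohort) -> pd.DataFrame:
        if not hasattr(self, "definitions_"):
            raise RuntimeError("SeverityScorer is not fitted")
        return score_cohort(X, self.score_names_, self.window,
                            self.definitions_, self.registry_)
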