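"""Cohort containers and plain-CSV input/output.

A cohort is a pair of tables:

``patients`` — one row per patient (index ``patient_id``): demographics,
admission descriptors, chronic-health flags (``flag_*`` columns), general
comorbidity columns used for the characteristics table, and the two vital
status outcomes (``died_60d``, ``died_inhospital``).

``physiology`` — one row per (patient, window, timestamp): vitals, labs,
blood-gas values, GCS, and the operational booleans ``ventilated`` and
``acute_renal_failure``. The ``window`` column tags the raw measurement
epoch, ``ed`` or ``icu_24h``; derived scoring windows (``ed_triage``,
``ed_worst``, ``icu_24h_worst``) are produced by the engine. Missing values
are empty CSV fields / NaN in memory.

Values outside the plausibility bounds declared in the variable registry are
rejected at ingest rather than silently converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .defs import VariableSpec, load_variable_registry

MEASUREMENT_WINDOWS = ("ed", "icu_24h")
SNAPSHOT_WINDOWS = ("ed_triage", "ed_worst", "icu_24h_worst")

CHRONIC_FLAGS = (
    "metastatic_cancer",
    "hematologic_malignancy",
    "immunosuppressed",
    "aids",
    "hepatic_failure_or_cirrhosis",
    "chronic_organ_insufficiency",
)

#: comorbidity columns summarised in the characteristics table
COMORBIDITIES = (
    "hypertension",
    "diabetes",
    "chronic_lung_disease",
    "malignancy",
    "congestive_heart_failure",
    "coronary_artery_disease",
    "chronic_liver_disease",
    "esrd",
)

ADMISSION_CATEGORIES = ("nonoperative", "elective_postoperative",
                        "emergency_postoperative")
SEXES = ("male", "female", "other")
SERVICES = ("medicine", "surgery", "cardiology", "other")

PATIENT_COLUMNS = (
    ("age", int),
    ("sex", str),
    ("admitting_service", str),
    ("micu", bool),
    ("admission_category", str),
    ("medical_admission", bool),
    ("unscheduled_surgery", bool),
    *((f"flag_{f}", bool) for f in CHRONIC_FLAGS),
    *((c, bool) for c in COMORBIDITIES),
    ("died_60d", bool),
    ("died_inhospital", bool),
)

PHYSIOLOGY_VARIABLES = (
    "temperature", "heart_rate", "respiratory_rate", "sbp", "map", "spo2",
    "gcs_total", "gcs_eye", "gcs_motor", "gcs_verbal", "fio2", "pao2",
    "aa_gradient", "ph", "pco2", "sodium", "potassium", "creatinine", "bun",
    "bicarbonate", "glucose", "bilirubin", "albumin", "hematocrit", "wbc",
    "urine_output_24h",
)
PHYSIOLOGY_FLAGS = ("acute_renal_failure", "ventilated")
PHYSIOLOGY_COLUMNS = ("patient_id", "window", "timestamp",
                      *PHYSIOLOGY_VARIABLES, *PHYSIOLOGY_FLAGS)


class SchemaError(ValueError):
    """A cohort table has an unknown/missing column or an invalid value."""


@dataclass
class PatientRecord:
    """One patient's demographics, admission descriptors and outcomes."""

    patient_id: str
    age: int
    sex: str
    admitting_service: str
    micu: bool
    admission_category: str
    medical_admission: bool
    unscheduled_surgery: bool
    chronic_flags: frozenset = frozenset()
    died_60d: bool = False
    died_inhospital: bool = False

    def __post_init__(self) -> None:
        if self.age < 18:
            raise SchemaError(f"{self.patient_id}: age {self.age} < 18")
        if self.admission_category not in ADMISSION_CATEGORIES:
            raise SchemaError(
                f"{self.patient_id}: bad admission_category "
                f"{self.admission_category!r}")
        if self.sex not in SEXES:
            raise SchemaError(f"{self.patient_id}: bad sex {self.sex!r}")
        unknown = set(self.chronic_flags) - set(CHRONIC_FLAGS)
        if unknown:
            raise SchemaError(f"{self.patient_id}: unknown flags {unknown}")


@dataclass
class PhysiologySnapshot:
    """One window's physiology for one patient; every field optional."""

    window: str
    timestamp: float | None = None
    values: dict = field(default_factory=dict)
    acute_renal_failure: bool | None = None
    ventilated: bool | None = None

    def get(self, var: str) -> float:
        v = self.values.get(var)
        return np.nan if v is None else v


def validate_physiology(physio: pd.DataFrame,
                        registry: Mapping[str, VariableSpec] | None = None) -> None:
    """Reject out-of-bounds values and inconsistent GCS components."""
    registry = registry or load_variable_registry()
    bad_win = set(physio["window"]) - set(MEASUREMENT_WINDOWS) - set(SNAPSHOT_WINDOWS)
    if bad_win:
        raise SchemaError(f"unknown window tags {sorted(bad_win)}")
    for var, spec in registry.items():
        if var not in physio.columns:
            continue
        v = pd.to_numeric(physio[var], errors="coerce")
        bad = (v < spec.lo) | (v > spec.hi)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise SchemaError(
                f"{var}={physio[var].iloc[i]} outside plausibility bounds "
                f"[{spec.lo}, {spec.hi}] (row {i})")
    comp = ["gcs_eye", "gcs_motor", "gcs_verbal"]
    if all(c in physio.columns for c in comp) and "gcs_total" in physio.columns:
        have = physio[comp].notna().all(axis=1) & physio["gcs_total"].notna()
        if have.any():
            tot = physio.loc[have, comp].sum(axis=1)
            mism = tot != physio.loc[have, "gcs_total"]
            if mism.any():
                pid = physio.loc[have].loc[mism, "patient_id"].iloc[0]
                raise SchemaError(f"{pid}: gcs_total != eye+motor+verbal")


@dataclass
class Cohort:
    """A patients table and a physiology table, validated together."""

    patients: pd.DataFrame
    physiology: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.patients
        if p.index.name != "patient_id":
            if "patient_id" in p.columns:
                p = p.set_index("patient_id")
                self.patients = p
            else:
                raise SchemaError("patients table needs a patient_id column/index")
        missing = {c for c, _ in PATIENT_COLUMNS} - set(p.columns)
        if missing:
            raise SchemaError(f"patients table missing columns {sorted(missing)}")
        unknown = set(p.columns) - {c for c, _ in PATIENT_COLUMNS}
        if unknown:
            raise SchemaError(f"patients table has unknown columns {sorted(unknown)}")
        if (p["age"] < 18).any():
            raise SchemaError("ages below 18 present (cohort is adults only)")
        bad = set(p["admission_category"]) - set(ADMISSION_CATEGORIES)
        if bad:
            raise SchemaError(f"bad admission categories {sorted(bad)}")
        ph = self.physiology
        unknown = set(ph.columns) - set(PHYSIOLOGY_COLUMNS)
        if unknown:
            raise SchemaError(f"physiology table has unknown columns {sorted(unknown)}")
        for c in ("patient_id", "window"):
            if c not in ph.columns:
                raise SchemaError(f"physiology table missing column {c}")
        orphans = set(ph["patient_id"]) - set(p.index)
        if orphans:
            raise SchemaError(f"physiology rows for unknown patients {sorted(orphans)[:5]}")
        validate_physiology(ph)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def subset(self, patient_ids: Iterable[str]) -> "Cohort":
        ids = list(patient_ids)
        return Cohort(
            self.patients.loc[ids].copy(),
            self.physiology[self.physiology["patient_id"].isin(ids)].copy(),
        )

    def micu_subset(self) -> "Cohort":
        return self.subset(self.patients.index[self.patients["micu"].astype(bool)])

    def record(self, patient_id: str) -> PatientRecord:
        row = self.patients.loc[patient_id]
        flags = frozenset(f for f in CHRONIC_FLAGS if bool(row[f"flag_{f}"]))
        return PatientRecord(
            patient_id=patient_id, age=int(row["age"]), sex=row["sex"],
            admitting_service=row["admitting_service"], micu=bool(row["micu"]),
            admission_category=row["admission_category"],
            medical_admission=bool(row["medical_admission"]),
            unscheduled_surgery=bool(row["unscheduled_surgery"]),
            chronic_flags=flags, died_60d=bool(row["died_60d"]),
            died_inhospital=bool(row["died_inhospital"]),
        )


_BOOL_PATIENT_COLS = [c for c, t in PATIENT_COLUMNS if t is bool]


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as ``patients.csv`` + ``physiology.csv`` under a directory.

    Missing values are written as empty fields; booleans as 0/1.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pats = cohort.patients.copy()
    for c in _BOOL_PATIENT_COLS:
        pats[c] = pats[c].astype(int)
    pats.to_csv(path / "patients.csv")
    phys = cohort.physiology.copy()
    for c in PHYSIOLOGY_FLAGS:
        if c in phys.columns:
            phys[c] = phys[c].map(lambda x: "" if pd.isna(x) else str(int(x)))
    phys.to_csv(path / "physiology.csv", index=False)


def read_cohort_csv(path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort_csv`."""
    path = Path(path)
    pats = pd.read_csv(path / "patients.csv", index_col="patient_id")
    unknown = set(pats.columns) - {c for c, _ in PATIENT_COLUMNS}
    if unknown:
        raise SchemaError(f"patients.csv has unknown columns {sorted(unknown)}")
    for c in _BOOL_PATIENT_COLS:
        if c in pats.columns:
            pats[c] = pats[c].astype(bool)
    pats.index = pats.index.astype(str)
    phys = pd.read_csv(path / "physiology.csv", dtype={"patient_id": str})
    unknown = set(phys.columns) - set(PHYSIOLOGY_COLUMNS)
    if unknown:
        raise SchemaError(f"physiology.csv has unknown columns {sorted(unknown)}")
    for c in PHYSIOLOGY_FLAGS:
        if c in phys.columns:
            phys[c] = pd.to_numeric(phys[c], errors="coerce")
    return Cohort(pats, phys)
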