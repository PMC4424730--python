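"""Synthetic ICU-admitted-from-ED cohort generator.

A single latent severity factor z ~ N(0,1) per patient drives both 60-day
mortality, via logit P(death) = alpha + beta z with alpha solved so expected
mortality hits the target rate, and every physiologic variable, via window
latents

    u_ed  = z + noise_ed
    u_icu = (1 + d) z + shift + noise_icu,     d = icu_extra_derangement

with the window noise variances solved so corr(u_ed, u_icu) equals the
configured within-patient correlation. Each variable's value is its normal
reference plus direction x effect x u plus measurement noise, clipped to the
plausibility bounds; two-tailed variables (temperature, sodium, ...) draw a
per-patient excursion direction from the registry's tail weights. Because
every score is built from overlapping functions of the same latent, the
scores are correlated across patients — the structure the DeLong machinery
is there to handle — and the ICU window carries more severity signal than
the ED window, so ICU-window scores discriminate at least as well on
average.

Demographics, chronic-health flags and comorbidities approximate the study
cohort's marginals (67% medicine / MICU, ~51% male, age 65 +/- 17, 60%
hypertension, ...). Missingness is per-variable, per-window,
missing-completely-at-random, concentrated by default in blood-gas values
and the missing-as-normal labs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special

from .cohort import (CHRONIC_FLAGS, COMORBIDITIES, Cohort,
                     PHYSIOLOGY_VARIABLES)
from .defs import VariableSpec, load_variable_registry

__all__ = ["CohortSpec", "generate_cohort"]

# marginal frequencies emulating the study cohort's characteristics table
_SERVICE_P = {"medicine": 0.67, "cardiology": 0.15, "surgery": 0.045, "other": 0.135}
_SEX_P = {"male": 0.51, "female": 0.485, "other": 0.005}
_COMORBIDITY_P = {
    "hypertension": 0.60, "diabetes": 0.33, "chronic_lung_disease": 0.31,
    "malignancy": 0.26, "congestive_heart_failure": 0.19,
    "coronary_artery_disease": 0.18, "chronic_liver_disease": 0.06,
    "esrd": 0.09,
}
_CHRONIC_FLAG_P = {
    "metastatic_cancer": 0.08, "hematologic_malignancy": 0.05,
    "immunosuppressed": 0.16, "aids": 0.02,
    "hepatic_failure_or_cirrhosis": 0.06, "chronic_organ_insufficiency": 0.22,
}

#: default per-variable missingness as (ed rate, icu rate); unlisted
#: variables use (0.0, 0.0). GCS is never measured in the ED (the study
#: took it from the ICU-admission exam); urine output needs a 24 h ICU stay.
_DEFAULT_MISSINGNESS: dict[str, tuple[float, float]] = {
    "ph": (0.35, 0.02), "pco2": (0.35, 0.02), "pao2": (0.30, 0.015),
    "fio2": (0.08, 0.01),
    "albumin": (0.40, 0.25), "bilirubin": (0.25, 0.12),
    "glucose": (0.02, 0.005), "bicarbonate": (0.02, 0.005),
    "wbc": (0.01, 0.005), "sodium": (0.01, 0.005), "potassium": (0.01, 0.005),
    "creatinine": (0.01, 0.005), "bun": (0.01, 0.005), "hematocrit": (0.01, 0.005),
    "temperature": (0.005, 0.002), "heart_rate": (0.002, 0.002),
    "respiratory_rate": (0.005, 0.002), "sbp": (0.002, 0.002),
    "map": (0.08, 0.005), "spo2": (0.005, 0.002),
    "gcs_total": (1.0, 0.002), "urine_output_24h": (1.0, 0.01),
}


@dataclass
class CohortSpec:
    """Generative parameters for one synthetic cohort.

    ``severity_effect`` scales every variable's registry derangement slope
    (0 severs the link between physiology/age and the latent severity, so
    all scores become uninformative); ``mortality_slope`` is the latent's
    coefficient on the death logit.
    """

    n_patients: int = 227
    mortality_rate: float = 57 / 227
    micu_fraction: float = 152 / 227
    severity_effect: float = 1.0
    severity_effect_overrides: Mapping[str, float] = field(default_factory=dict)
    age_effect: float = 6.0  # years per unit latent severity
    mortality_slope: float = 1.5
    ed_icu_correlation: float = 0.7
    icu_extra_derangement: float = 0.3
    missingness_rates: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 20:
            raise ValueError("n_patients must be >= 20")
        if not 0 < self.mortality_rate < 1:
            raise ValueError("mortality target must lie strictly in (0, 1)")
        if not 0 < self.micu_fraction <= 1:
            raise ValueError("micu_fraction must lie in (0, 1]")
        if not 0 < self.ed_icu_correlation < 1:
            raise ValueError("ed_icu_correlation must lie in (0, 1)")
        if self.icu_extra_derangement < 0:
            raise ValueError("icu_extra_derangement must be non-negative")
        for var, (pe, pi) in self.missingness_rates.items():
            if not (0 <= pe <= 1 and 0 <= pi <= 1):
                raise ValueError(f"missingness for {var} outside [0, 1]")


def _solve_intercept(target: float, slope: float) -> float:
    """alpha with E_z[expit(alpha + slope z)] = target, z ~ N(0,1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w = weights / weights.sum()

    def mean_risk(alpha: float) -> float:
        return float(w @ special.expit(alpha + slope * nodes))

    return optimize.brentq(lambda a: mean_risk(a) - target, -30, 30, xtol=1e-10)


def _effect(spec: CohortSpec, var: str, vs: VariableSpec) -> float:
    base = spec.severity_effect_overrides.get(var)
    scale = base if base is not None else vs.effect
    return spec.severity_effect * scale


def _derangement(u: np.ndarray) -> np.ndarray:
    """Non-negative, monotone derangement magnitude: softplus of the latent.

    Healthier-than-average patients (u < 0) sit near normal physiology
    rather than excursing past it in the opposite direction.
    """
    return np.logaddexp(0.0, u)


def _draw_values(rng: np.random.Generator, registry, spec: CohortSpec,
                 u: np.ndarray, direction: Mapping[str, np.ndarray],
                 variables) -> dict[str, np.ndarray]:
    mag = _derangement(u)
    out = {}
    for var in variables:
        vs = registry[var]
        eff = _effect(spec, var, vs)
        v = vs.normal + direction[var] * eff * mag \
            + rng.normal(0.0, vs.noise_sd, len(u))
        v = np.clip(v, vs.lo, vs.hi)
        if vs.integer:
            v = np.round(v)
        out[var] = v
    return out


def generate_cohort(spec: CohortSpec | None = None,
                    registry=None) -> Cohort:
    """Draw one synthetic cohort (deterministic given ``spec.seed``)."""
    spec = spec or CohortSpec()
    spec.validate()
    registry = registry or load_variable_registry()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    pid = np.array([f"P{i:04d}" for i in range(n)])

    # latent severity and outcomes
    z = rng.normal(size=n)
    alpha = _solve_intercept(spec.mortality_rate, spec.mortality_slope)
    p_death = special.expit(alpha + spec.mortality_slope * z)
    died_60d = rng.random(n) < p_death
    died_inhospital = died_60d & (rng.random(n) < 0.85)

    # demographics approximating the study's characteristics table
    service = rng.choice(list(_SERVICE_P), p=list(_SERVICE_P.values()), size=n)
    # the MICU subgroup is the medicine-service subgroup; rebalance the
    # service draw so its share matches the configured MICU fraction
    med = service == "medicine"
    target_med = int(round(spec.micu_fraction * n))
    idx_med, idx_other = np.flatnonzero(med), np.flatnonzero(~med)
    if len(idx_med) > target_med:
        flip = rng.choice(idx_med, len(idx_med) - target_med, replace=False)
        service[flip] = rng.choice(["cardiology", "other"], size=len(flip))
    elif len(idx_med) < target_med:
        flip = rng.choice(idx_other, target_med - len(idx_med), replace=False)
        service[flip] = "medicine"
    micu = service == "medicine"

    sex = rng.choice(list(_SEX_P), p=list(_SEX_P.values()), size=n)
    age = 65.0 + spec.severity_effect * spec.age_effect * z \
        + rng.normal(0.0, 16.0, n)
    age = np.clip(np.round(age), 18, 105).astype(int)

    category = np.where(
        service == "surgery",
        np.where(rng.random(n) < 0.5, "elective_postoperative",
                 "emergency_postoperative"),
        "nonoperative")
    patients = pd.DataFrame({
        "age": age, "sex": sex, "admitting_service": service, "micu": micu,
        "admission_category": category,
        "medical_admission": category == "nonoperative",
        "unscheduled_surgery": category == "emergency_postoperative",
        **{f"flag_{f}": rng.random(n) < p for f, p in _CHRONIC_FLAG_P.items()},
        **{c: rng.random(n) < p for c, p in _COMORBIDITY_P.items()},
        "died_60d": died_60d, "died_inhospital": died_inhospital,
    }, index=pd.Index(pid, name="patient_id"))
    assert set(f for f in CHRONIC_FLAGS) == set(_CHRONIC_FLAG_P)
    assert set(COMORBIDITIES) == set(_COMORBIDITY_P)

    # window latents: u_w = c_w z + sqrt(1 - c_w^2) noise, unit variance.
    # The ICU window loads more on severity than the ED window (disease has
    # declared itself by 24 h), with the loadings' product keeping
    # corr(u_ed, u_icu) = ed_icu_correlation; icu_extra_derangement controls
    # the information asymmetry and adds a magnitude drift in the ICU.
    rho = spec.ed_icu_correlation
    d = spec.icu_extra_derangement
    c_icu = min(np.sqrt(rho) * (1.0 + d / 2.0), 0.99)
    c_ed = rho / c_icu
    u_ed = c_ed * z + np.sqrt(1 - c_ed ** 2) * rng.normal(size=n)
    u_icu = (1.0 + d / 2.0) * (c_icu * z
                               + np.sqrt(1 - c_icu ** 2) * rng.normal(size=n)) \
        + 0.5 * d

    # per-patient excursion direction, fixed across windows
    direction = {}
    for var, vs in registry.items():
        high = rng.random(n) < vs.p_high
        direction[var] = np.where(high, 1.0, -1.0)
    # a variable's derangement direction is "toward abnormal": for
    # below-normal excursions the sign flips
    for var in ("spo2", "gcs_total", "albumin", "urine_output_24h", "pao2"):
        direction[var] = -np.abs(direction[var])

    cont_vars = [v for v in PHYSIOLOGY_VARIABLES
                 if v in registry and v not in ("aa_gradient", "fio2")]

    rows = []
    gcs_admission = None
    for win, u, tag, ts in (("ed", u_ed, "ed", 0.0),
                            ("icu_a", u_icu, "icu_24h", 1.0),
                            ("icu_b", u_icu, "icu_24h", 13.0)):
        vals = _draw_values(rng, registry, spec, u, direction, cont_vars)
        # supplemental oxygen rises with severity; alveolar gas equation
        # then yields a physiologically consistent A-a gradient
        fio2 = np.clip(0.21 + _effect(spec, "fio2", registry["fio2"])
                       * _derangement(u)
                       + rng.normal(0, registry["fio2"].noise_sd, n),
                       0.21, 1.0)
        aa = np.clip(fio2 * 713.0 - vals["pco2"] / 0.8 - vals["pao2"], 0.0, 700.0)
        vals["fio2"] = fio2
        vals["aa_gradient"] = aa
        if win == "icu_a":
            gcs_admission = vals["gcs_total"]
        if win == "icu_b" and gcs_admission is not None:
            vals["gcs_total"] = gcs_admission  # GCS from the admission exam
        frame = pd.DataFrame({"patient_id": pid, "window": tag,
                              "timestamp": ts, **vals})
        frame["ventilated"] = (
            rng.random(n) < special.expit(-1.2 + 1.3 * u)).astype(float)
        frame["acute_renal_failure"] = (
            (rng.random(n) < special.expit(-2.5 + 1.2 * u))
            & (vals["creatinine"] > 1.5)).astype(float)
        rows.append(frame)

    physio = pd.concat(rows, ignore_index=True)

    # missingness: per patient, variable and window (both ICU rows share
    # one missingness draw so that "missing" means "not measured that day")
    for var, (p_ed, p_icu) in spec.missingness_rates.items():
        if var not in physio.columns:
            continue
        for tag, p_miss in (("ed", p_ed), ("icu_24h", p_icu)):
            if p_miss <= 0:
                continue
            miss = pd.Series(rng.random(n) < p_miss, index=pid)
            sel = physio["window"] == tag
            mask = physio.loc[sel, "patient_id"].map(miss).to_numpy()
            col = physio.loc[sel, var].to_numpy(dtype=float, copy=True)
            col[mask] = np.nan
            physio.loc[sel, var] = col

    # GCS components for patients with a measured total (canonical split)
    for c in ("gcs_eye", "gcs_motor", "gcs_verbal"):
        physio[c] = np.nan

    return Cohort(patients, physio)
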