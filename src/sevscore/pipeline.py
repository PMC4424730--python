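"""End-to-end study replication on a cohort (synthetic or user-supplied).

Products mirror the study's reporting:

* characteristics table — per-characteristic overall / survivor / non-survivor
  summaries with unpaired t, chi-square or Fisher tests;
* discrimination table — AUC (95% CI) per score x window x subgroup, the
  k-sample AUC-equality test on complete cases, pairwise tests against the
  best-AUC ICU score, and ROC plot data;
* calibration table — Hosmer-Lemeshow p (ten groups, probabilities from a
  univariate logistic refit per score) and decile plot data;
* a machine-readable summary JSON plus CSV tables, deterministic given the
  cohort and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import COMORBIDITIES, Cohort, read_cohort_csv
from .defs import ED_SCORES, ICU_SCORES, SCORE_NAMES, load_score_definitions
from .engine import completeness_filter, score_cohort
from .simulate import CohortSpec, generate_cohort
from .stats import (ScoreRecalibrator, auc_mannwhitney, calibration_deciles,
                    chi_square_2x2, compare_aucs, fisher_exact_2x2,
                    hosmer_lemeshow, pairwise_auc_tests, two_sample_t_raw)

log = logging.getLogger("sevscore")

__all__ = ["RunConfig", "run_characteristics_table", "run_discrimination",
           "run_calibration", "run_full_study"]


@dataclass
class RunConfig:
    """Configuration for a full study run."""

    cohort_path: str | None = None      # None: simulate
    scores: Sequence[str] = SCORE_NAMES
    endpoint: str = "died_60d"          # or died_inhospital
    subgroups: Sequence[str] = ("all", "micu")
    ed_window_mode: str = "default"     # 'default' or 'icu' (sensitivity)
    output_dir: str = "sevscore_out"
    seed: int = 0
    n_patients: int = 227
    report_formats: Sequence[str] = ("csv", "json")

    def __post_init__(self) -> None:
        if self.endpoint not in ("died_60d", "died_inhospital"):
            raise ValueError(f"bad endpoint {self.endpoint!r}")
        bad = set(self.subgroups) - {"all", "micu"}
        if bad:
            raise ValueError(f"bad subgroups {sorted(bad)}")


# ---------------------------------------------------------------------------
# characteristics table

def _binary_row(name, x, y):
    a = int((x & y).sum())        # outcome+, exposed
    b = int((~x & y).sum())
    c = int((x & ~y).sum())
    d = int((~x & ~y).sum())
    n = len(x)
    tab = np.array([[a, c], [b, d]], dtype=float)
    degenerate = x.all() or (~x).all() or y.all() or (~y).all()
    if degenerate:
        return dict(test="degenerate", p_value=1.0)
    expected = np.outer(tab.sum(1), tab.sum(0)) / n
    if (expected < 5).any():
        return dict(test="fisher", p_value=fisher_exact_2x2(a, c, b, d))
    return dict(test="chi2", p_value=chi_square_2x2(a, c, b, d)[1])


def run_characteristics_table(cohort: Cohort,
                              endpoint: str = "died_60d") -> pd.DataFrame:
    """Summaries and tests of patient characteristics by vital status.

    Continuous characteristics: mean +/- SD and an unpaired pooled-variance
    t test. Binary: n (%) and Pearson chi-square without continuity
    correction, or Fisher's exact test when an expected count is below 5.
    Multi-level: r x c chi-square. Constant characteristics are reported
    with a degenerate flag and p = 1.
    """
    if cohort.n_patients == 0:
        raise ValueError("empty cohort")
    p = cohort.patients
    y = p[endpoint].astype(bool)
    rows = []

    def fmt_cont(v):
        return f"{v.mean():.0f} ± {v.std(ddof=1):.0f}"

    v = p["age"].astype(float)
    t, df, pval = two_sample_t_raw(v[~y], v[y])
    rows.append({"characteristic": "age", "type": "continuous",
                 "overall": fmt_cont(v), "alive": fmt_cont(v[~y]),
                 "dead": fmt_cont(v[y]), "test": "t", "p_value": pval})

    for name, col in (("sex", "sex"), ("admitting_service", "admitting_service")):
        tab = pd.crosstab(p[col], y)
        if tab.shape[1] < 2 or (tab.shape[0] < 2):
            test, pval = "degenerate", 1.0
        else:
            _, pval, _, _ = sps.chi2_contingency(tab.to_numpy())
            test = "chi2_rxc"
        rows.append({"characteristic": name, "type": "categorical",
                     "overall": "/".join(f"{k}:{int(c)}"
                                         for k, c in p[col].value_counts().items()),
                     "alive": "", "dead": "", "test": test, "p_value": pval})

    binaries = list(COMORBIDITIES) + ["flag_immunosuppressed", "micu"]
    for name in binaries:
        if name not in p.columns:
            log.warning("characteristic %s absent from cohort; skipped", name)
            continue
        x = p[name].astype(bool)
        res = _binary_row(name, x, y)
        rows.append({
            "characteristic": name.removeprefix("flag_"), "type": "binary",
            "overall": f"{int(x.sum())} ({100 * x.mean():.0f}%)",
            "alive": f"{int((x & ~y).sum())} ({100 * x[~y].mean():.0f}%)",
            "dead": f"{int((x & y).sum())} ({100 * x[y].mean():.0f}%)",
            **res})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# discrimination (AUC table + ROC plot data)

def _window_map(scores: Sequence[str], ed_window_mode: str) -> dict | None:
    if ed_window_mode == "default":
        return None
    if ed_window_mode == "icu":
        return {s: "icu_24h_worst" for s in scores}
    raise ValueError(f"bad ed_window_mode {ed_window_mode!r}")


def run_discrimination(cohort: Cohort, scores: Sequence[str] = SCORE_NAMES,
                       endpoint: str = "died_60d",
                       ed_window_mode: str = "default",
                       definitions=None) -> dict:
    """AUC with 95% CI per score, overall equality test, pairwise tests.

    All statistics are computed on the complete cases common to every
    requested score (the equality test's requirement); the complete-case n
    is reported.
    """
    scores = list(scores)
    if len(scores) < 2:
        raise ValueError("need at least two scores")
    definitions = definitions or load_score_definitions()
    values, meta = score_cohort(cohort, scores,
                                window=_window_map(scores, ed_window_mode),
                                definitions=definitions, with_meta=True)
    y_all = cohort.patients[endpoint].astype(int)
    complete = values.dropna()
    y = y_all.loc[complete.index]
    rows, roc_data = [], {}
    for s in scores:
        roc = auc_mannwhitney(complete[s].to_numpy(), y.to_numpy(), s)
        rows.append({"score": s, "window": meta[s]["window"],
                     "n": len(complete), "auc": roc.auc, "auc_se": roc.auc_se,
                     "ci_lo": roc.ci95[0], "ci_hi": roc.ci95[1]})
        roc_data[s] = roc.roc_points
    table = pd.DataFrame(rows)
    eq = compare_aucs(complete[scores], y.to_numpy())
    icu_present = [s for s in scores if s in ICU_SCORES]
    pairwise = None
    if icu_present:
        best = table.set_index("score").loc[icu_present, "auc"].idxmax()
        pairwise = pairwise_auc_tests(complete[scores], y.to_numpy(),
                                      reference=best)
        pairwise.insert(0, "reference", best)
    return {"table": table, "equality": eq, "pairwise": pairwise,
            "roc_points": roc_data, "n_complete": len(complete),
            "n_total": cohort.n_patients}


# ---------------------------------------------------------------------------
# calibration (HL table + decile plot data)

def run_calibration(cohort: Cohort, scores: Sequence[str] = SCORE_NAMES,
                    endpoint: str = "died_60d",
                    ed_window_mode: str = "default",
                    definitions=None) -> dict:
    """Hosmer-Lemeshow (ten groups, refit univariate logistic) per score.

    Mirrors the study's usage: each score is recalibrated to the analysis
    cohort by univariate logistic regression, the HL statistic is applied
    to the fitted probabilities with groups - 2 degrees of freedom, and the
    decile table provides the calibration plot data. p < 0.05 is flagged as
    a calibration failure; non-convergent fits are skipped with a
    diagnostic.
    """
    scores = list(scores)
    definitions = definitions or load_score_definitions()
    values = score_cohort(cohort, scores,
                          window=_window_map(scores, ed_window_mode),
                          definitions=definitions)
    y_all = cohort.patients[endpoint].astype(int)
    rows, deciles, skipped = [], {}, {}
    for s in scores:
        x = values[s].dropna()
        y = y_all.loc[x.index].to_numpy()
        try:
            rec = ScoreRecalibrator().fit(x.to_numpy(), y)
            if not rec.converged_:
                raise RuntimeError("logistic recalibration did not converge"
                                   + (" (separation)" if rec.separation_ else ""))
            pred = rec.predict_proba(x.to_numpy())[:, 1]
            hl = hosmer_lemeshow(pred, y, groups=10, fitted=True, score_name=s)
        except (RuntimeError, ValueError) as exc:
            log.warning("calibration skipped for %s: %s", s, exc)
            skipped[s] = str(exc)
            continue
        rows.append({"score": s, "n": len(x),
                     "intercept": rec.intercept_, "slope": rec.slope_,
                     "hl_statistic": hl.hl_statistic, "df": hl.df,
                     "p_value": hl.p_value,
                     "calibration_failure": hl.p_value < 0.05})
        deciles[s] = calibration_deciles(pred, y)
    return {"table": pd.DataFrame(rows), "deciles": deciles, "skipped": skipped}


# ---------------------------------------------------------------------------
# full study

def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_full_study(config: RunConfig) -> dict:
    """Run every analysis product and write the report bundle.

    Returns the bundle as a dict; when ``output_dir`` is set, also writes
    CSV tables, ROC/decile plot data and ``summary.json`` there, plus the
    exclusion log. Deterministic given the cohort and seed.
    """
    if config.cohort_path is not None:
        cohort = read_cohort_csv(config.cohort_path)
        log.info("loaded cohort of %d patients from %s",
                 cohort.n_patients, config.cohort_path)
    else:
        cohort = generate_cohort(CohortSpec(n_patients=config.n_patients,
                                            seed=config.seed))
        log.info("simulated cohort of %d patients (seed %d)",
                 cohort.n_patients, config.seed)
    definitions = load_score_definitions()
    scores = list(config.scores)
    eligible, excl_log = completeness_filter(
        cohort,
        definitions,
        icu_scores=[s for s in scores if s in ICU_SCORES],
        ed_scores=[s for s in scores if s in ED_SCORES])
    log.info("complete cases: %d of %d (%d excluded)", eligible.n_patients,
             cohort.n_patients, cohort.n_patients - eligible.n_patients)

    bundle: dict = {
        "config": asdict(config) | {"scores": scores},
        "n_screened": cohort.n_patients,
        "n_eligible": eligible.n_patients,
        "n_excluded_icu_stage": int(excl_log.loc[excl_log["stage"] == "icu",
                                                 "patient_id"].nunique()),
        "n_excluded_ed_stage": int(excl_log.loc[excl_log["stage"] == "ed",
                                                "patient_id"].nunique()),
        "subgroups": {},
    }
    bundle["characteristics"] = run_characteristics_table(eligible,
                                                          config.endpoint)
    for sub in config.subgroups:
        sub_cohort = eligible if sub == "all" else eligible.micu_subset()
        entry = {"n": sub_cohort.n_patients}
        # run the design windows and the ED-scores-on-ICU-data sensitivity
        for mode in ("default", "icu"):
            disc = run_discrimination(sub_cohort, scores, config.endpoint,
                                      ed_window_mode=mode,
                                      definitions=definitions)
            cal = run_calibration(sub_cohort, scores, config.endpoint,
                                  ed_window_mode=mode, definitions=definitions)
            entry[f"discrimination_{mode}"] = {
                "table": disc["table"],
                "equality_chi2": disc["equality"].chi2,
                "equality_df": disc["equality"].df,
                "equality_p": disc["equality"].p_value,
                "pairwise": disc["pairwise"],
                "n_complete": disc["n_complete"],
            }
            entry[f"calibration_{mode}"] = {"table": cal["table"],
                                            "skipped": cal["skipped"]}
            entry[f"roc_points_{mode}"] = disc["roc_points"]
            entry[f"deciles_{mode}"] = cal["deciles"]
        bundle["subgroups"][sub] = entry

    if config.output_dir:
        _write_bundle(bundle, excl_log, Path(config.output_dir))
    return bundle


def _write_bundle(bundle: dict, excl_log: pd.DataFrame, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    excl_log.to_csv(outdir / "exclusions.csv", index=False)
    bundle["characteristics"].to_csv(outdir / "characteristics.csv", index=False)
    for sub, entry in bundle["subgroups"].items():
        for mode in ("default", "icu"):
            key = f"discrimination_{mode}"
            if key not in entry:
                continue
            entry[key]["table"].to_csv(
                outdir / f"discrimination_{sub}_{mode}.csv", index=False)
            entry[f"calibration_{mode}"]["table"].to_csv(
                outdir / f"calibration_{sub}_{mode}.csv", index=False)
            roc_rows = []
            for s, pts in entry[f"roc_points_{mode}"].items():
                for fpr, tpr in pts:
                    roc_rows.append({"score": s, "fpr": fpr, "tpr": tpr})
            pd.DataFrame(roc_rows).to_csv(
                outdir / f"roc_points_{sub}_{mode}.csv", index=False)
            dec_rows = []
            for s, tab in entry[f"deciles_{mode}"].items():
                t = tab.copy()
                t.insert(0, "score", s)
                dec_rows.append(t)
            if dec_rows:
                pd.concat(dec_rows).to_csv(
                    outdir / f"calibration_deciles_{sub}_{mode}.csv", index=False)
            from .plots import render_calibration, render_roc
            render_roc(entry[f"roc_points_{mode}"],
                       outdir / f"roc_{sub}_{mode}.png")
            if entry[f"deciles_{mode}"]:
                render_calibration(entry[f"deciles_{mode}"],
                                   outdir / f"calibration_{sub}_{mode}.png")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=1, sort_keys=True)
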