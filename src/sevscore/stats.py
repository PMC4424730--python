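"""Discrimination and calibration statistics.

Authored here: the tie-corrected Mann-Whitney AUC with its ROC curve, the
DeLong placement-value covariance estimator for correlated AUCs, the
k-sample AUC-equality chi-square, pairwise AUC
z-tests, the Hosmer-Lemeshow ten-group statistic and calibration deciles.

Delegated to established libraries behind the same function surface:
unpaired t, Pearson chi-square (no continuity correction) and Fisher's exact
test (scipy.stats); maximum-likelihood univariate logistic regression
(statsmodels, Newton-Raphson).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

__all__ = [
    "RocAnalysis", "AucEqualityTest", "CalibrationResult", "LogisticFit",
    "ScoreRecalibrator", "fit_univariate_logistic", "auc_mannwhitney",
    "delong_covariance", "compare_aucs", "pairwise_auc_tests",
    "hosmer_lemeshow", "calibration_deciles", "two_sample_t",
    "two_sample_t_raw", "chi_square_2x2", "fisher_exact_2x2",
]


# ---------------------------------------------------------------------------
# result containers

@dataclass
class RocAnalysis:
    score_name: str
    n_pos: int
    n_neg: int
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    roc_points: np.ndarray  # (m, 2) array of (fpr, tpr)


@dataclass
class AucEqualityTest:
    scores_compared: list[str]
    chi2: float
    df: int
    p_value: float
    aucs: np.ndarray
    covariance: np.ndarray


@dataclass
class CalibrationResult:
    score_name: str
    groups: pd.DataFrame  # n, mean_predicted, observed_deaths, expected_deaths
    hl_statistic: float
    df: int
    p_value: float


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    converged: bool
    iterations: int
    log_likelihood: float
    intercept_se: float = np.nan
    slope_se: float = np.nan

    def predict(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(self.intercept + self.slope * np.asarray(x, float))))


# ---------------------------------------------------------------------------
# univariate logistic recalibration

class ScoreRecalibrator(BaseEstimator):
    """Univariate logistic regression of a binary outcome on a score.

    sklearn-style estimator around a Newton-Raphson maximum-likelihood fit
    (statsmodels). Fitted attributes: ``intercept_``, ``slope_``,
    ``converged_``, ``n_iter_``, ``log_likelihood_``.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y) -> "ScoreRecalibrator":
        import statsmodels.api as sm

        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        if len(x) < 10:
            raise ValueError("need at least 10 observations")
        classes = np.unique(y)
        if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
            raise ValueError("outcomes must contain both classes (0 and 1)")
        design = sm.add_constant(x)
        model = sm.Logit(y, design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(method="newton", tol=self.tol,
                                maxiter=self.max_iter, disp=False)
                converged = bool(res.mle_retvals.get("converged", False))
            except Exception:  # perfect separation raises in statsmodels
                res = None
                converged = False
        if res is None or not np.isfinite(res.params).all():
            self.intercept_, self.slope_ = np.nan, np.nan
            self.converged_ = False
            self.n_iter_ = self.max_iter
            self.log_likelihood_ = np.nan
            self.separation_ = True
            return self
        grad = model.score(res.params)
        self.separation_ = False
        if np.linalg.norm(grad) > 1e-6:
            converged = False
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.converged_ = converged
        self.n_iter_ = int(res.mle_retvals.get("iterations", 0))
        self.log_likelihood_ = float(res.llf)
        self.bse_ = np.asarray(res.bse, dtype=float)
        return self

    def predict_proba(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).reshape(-1)
        p1 = 1.0 / (1.0 + np.exp(-(self.intercept_ + self.slope_ * x)))
        return np.column_stack([1 - p1, p1])

    def to_fit(self) -> LogisticFit:
        se = getattr(self, "bse_", np.array([np.nan, np.nan]))
        return LogisticFit(self.intercept_, self.slope_, self.converged_,
                           self.n_iter_, self.log_likelihood_, se[0], se[1])


def fit_univariate_logistic(x, y) -> LogisticFit:
    """MLE fit of ``logit P(y=1) = b0 + b1 x``.

    A constant ``x`` gives slope 0 and intercept logit(mean(y)); perfect
    separation is flagged via ``converged=False``.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    if np.ptp(x) == 0:  # no information: closed form
        ybar = float(np.mean(y))
        return LogisticFit(float(np.log(ybar / (1 - ybar))), 0.0, True, 0,
                           float(len(x) * (ybar * np.log(ybar)
                                           + (1 - ybar) * np.log(1 - ybar))))
    return ScoreRecalibrator().fit(x, y).to_fit()


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong

def _check_binary(y) -> np.ndarray:
    y = np.asarray(y, dtype=float).reshape(-1)
    if not np.isin(np.unique(y), [0.0, 1.0]).all():
        raise ValueError("outcomes must be 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    return y


def _roc_points(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Empirical ROC polygon from (0,0) to (1,1), one vertex per threshold."""
    order = np.argsort(-scores, kind="mergesort")
    s, yy = scores[order], y[order]
    distinct = np.r_[np.diff(s) != 0, True]
    tps = np.cumsum(yy)[distinct]
    fps = np.cumsum(1 - yy)[distinct]
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    return np.column_stack([fpr, tpr])


def _midrank_placements(scores: np.ndarray, y: np.ndarray):
    """DeLong structural components (placement values) for one score."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = sps.rankdata(np.r_[pos, neg])  # midranks handle ties as 1/2
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - r_pos) / n          # P(neg < pos_i) with tie credit
    v01 = 1.0 - (all_r[m:] - r_neg) / m    # P(pos > neg_j) with tie credit
    return auc, v10, v01


def auc_mannwhitney(scores, outcomes, score_name: str = "",
                    ci: str = "normal") -> RocAnalysis:
    """Tie-corrected Mann-Whitney AUC with DeLong SE and 95% CI.

    The AUC is the probability that a randomly chosen positive outscores a
    randomly chosen negative, ties counting one half. The ROC polygon is
    also computed and its trapezoidal area checked against the rank
    statistic (they agree to numerical precision by construction).

    ``ci='normal'`` truncates the Wald interval to [0, 1];
    ``ci='logit'`` transforms it instead.
    """
    y = _check_binary(outcomes)
    s = np.asarray(scores, dtype=float).reshape(-1)
    if len(s) != len(y):
        raise ValueError("scores and outcomes must align")
    auc, v10, v01 = _midrank_placements(s, y)
    m, n = int(y.sum()), int((1 - y).sum())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    pts = _roc_points(s, y)
    trap = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    if abs(trap - auc) > 1e-10:
        raise AssertionError(
            f"ROC trapezoid area {trap} disagrees with rank AUC {auc}")
    z = sps.norm.ppf(0.975)
    if ci == "logit" and 0 < auc < 1:
        lo_ = np.log(auc / (1 - auc))
        se_l = se / (auc * (1 - auc))
        lo, hi = (1 / (1 + np.exp(-(lo_ - z * se_l))),
                  1 / (1 + np.exp(-(lo_ + z * se_l))))
    else:
        lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return RocAnalysis(score_name, m, n, float(auc), se, (float(lo), float(hi)), pts)


def delong_covariance(score_matrix, outcomes) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance for k correlated scores.

    ``score_matrix`` is (k, n) or a DataFrame with one column per score
    (transposed internally). Missing values are rejected: complete-case
    filter first.

    Returns (aucs shape (k,), covariance shape (k, k)).
    """
    if isinstance(score_matrix, pd.DataFrame):
        X = score_matrix.to_numpy(dtype=float).T
    else:
        X = np.asarray(score_matrix, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    y = _check_binary(outcomes)
    if X.shape[1] != len(y):
        raise ValueError("score matrix and outcomes must align")
    if np.isnan(X).any():
        raise ValueError("missing scores present; complete-case filter first")
    k = X.shape[0]
    m, n = int(y.sum()), int((1 - y).sum())
    aucs = np.empty(k)
    V10 = np.empty((k, m))
    V01 = np.empty((k, n))
    for i in range(k):
        aucs[i], V10[i], V01[i] = _midrank_placements(X[i], y)
    s10 = np.cov(V10) if m > 1 else np.zeros((k, k))
    s01 = np.cov(V01) if n > 1 else np.zeros((k, k))
    s10 = np.atleast_2d(s10)
    s01 = np.atleast_2d(s01)
    cov = s10 / m + s01 / n
    return aucs, cov


def compare_aucs(score_matrix, outcomes,
                 names: list[str] | None = None) -> AucEqualityTest:
    """DeLong k-sample test that all AUCs are equal.

    chi2 = (L a)' (L S L')^{-1} (L a) with L the successive-difference
    contrast matrix, S the DeLong covariance; df = k - 1. The statistic is
    invariant to the choice of full-rank contrast basis.
    """
    if isinstance(score_matrix, pd.DataFrame):
        names = names or list(score_matrix.columns)
    aucs, cov = delong_covariance(score_matrix, outcomes)
    k = len(aucs)
    if k < 2:
        raise ValueError("need at least two scores to compare")
    names = names or [f"score{i}" for i in range(k)]
    L = np.eye(k - 1, k) - np.eye(k - 1, k, 1)  # successive differences
    diff = L @ aucs
    S = L @ cov @ L.T
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        if np.allclose(diff, 0.0, atol=1e-12):
            # identical scores: no evidence against equality
            return AucEqualityTest(list(names), 0.0, k - 1, 1.0, aucs, cov)
        raise np.linalg.LinAlgError(
            f"contrast covariance is singular (condition number {cond:.3g})")
    chi2 = float(diff @ np.linalg.solve(S, diff))
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, k - 1))
    return AucEqualityTest(list(names), chi2, k - 1, p, aucs, cov)


def pairwise_auc_tests(score_matrix, outcomes, names: list[str] | None = None,
                       reference: str | int | None = None,
                       correction: str | None = None) -> pd.DataFrame:
    """Pairwise DeLong z-tests; optionally only each score vs a reference.

    ``correction="bonferroni"`` adds a ``p_adjusted`` column (off by
    default, matching the uncorrected reporting convention).
    """
    if isinstance(score_matrix, pd.DataFrame):
        names = names or list(score_matrix.columns)
    aucs, cov = delong_covariance(score_matrix, outcomes)
    k = len(aucs)
    names = names or [f"score{i}" for i in range(k)]
    if isinstance(reference, str):
        reference = names.index(reference)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            if reference is not None and reference not in (i, j):
                continue
            var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
            if var <= 0:
                z, p = (0.0, 1.0) if np.isclose(aucs[i], aucs[j]) else (np.inf, 0.0)
            else:
                z = (aucs[i] - aucs[j]) / np.sqrt(var)
                p = 2 * sps.norm.sf(abs(z))
            rows.append({"score_a": names[i], "score_b": names[j],
                         "auc_a": aucs[i], "auc_b": aucs[j],
                         "z": float(z), "p_value": float(p)})
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["p_adjusted"] = np.minimum(out["p_value"] * len(out), 1.0)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return out


# ---------------------------------------------------------------------------
# calibration

def _risk_groups(predicted: np.ndarray, n_groups: int) -> np.ndarray:
    """Group labels 0..g-1 by predicted risk, never splitting ties.

    Quantile-rank method: each distinct predicted value goes wholly to
    the group of its average rank, so group sizes can deviate from n/g.
    """
    n = len(predicted)
    order = np.argsort(predicted, kind="mergesort")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(n)
    # average rank within ties
    df = pd.Series(ranks).groupby(pd.Series(predicted)).transform("mean")
    g = np.floor(df.to_numpy() * n_groups / n).astype(int)
    return np.clip(g, 0, n_groups - 1)


def hosmer_lemeshow(predicted, outcomes, groups: int = 10,
                    fitted: bool = True,
                    score_name: str = "") -> CalibrationResult:
    """Hosmer-Lemeshow goodness-of-fit over risk-ordered groups.

    C-hat = sum_g (O_g - E_g)^2 / (E_g (1 - E_g / n_g)); df = groups - 2
    when the probabilities come from a model fitted on the same data
    (``fitted=True``, the usual case), groups - 0 for an externally fixed
    transform.
    """
    p = np.asarray(predicted, dtype=float).reshape(-1)
    y = np.asarray(outcomes, dtype=float).reshape(-1)
    if len(p) != len(y):
        raise ValueError("predicted and outcomes must align")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    if len(p) < groups:
        raise ValueError("need at least as many patients as groups")
    g = _risk_groups(p, groups)
    rows = []
    stat = 0.0
    for gi in range(groups):
        sel = g == gi
        n_g = int(sel.sum())
        if n_g == 0:
            continue
        e = float(p[sel].sum())
        o = float(y[sel].sum())
        mean_p = float(p[sel].mean())
        if e <= 1e-8 or e >= n_g - 1e-8:
            raise ValueError(
                f"degenerate group {gi}: expected deaths {e:.3g} of {n_g}")
        stat += (o - e) ** 2 / (e * (1 - e / n_g))
        rows.append({"group": gi, "n": n_g, "mean_predicted": mean_p,
                     "observed_deaths": o, "expected_deaths": e})
    table = pd.DataFrame(rows)
    df = len(rows) - 2 if fitted else len(rows)
    pval = float(sps.chi2.sf(stat, df))
    return CalibrationResult(score_name, table, float(stat), df, pval)


def calibration_deciles(predicted, outcomes) -> pd.DataFrame:
    """Mean predicted vs observed mortality by decile of predicted risk."""
    p = np.asarray(predicted, dtype=float).reshape(-1)
    y = np.asarray(outcomes, dtype=float).reshape(-1)
    if len(p) != len(y):
        raise ValueError("predicted and outcomes must align")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    g = _risk_groups(p, 10)
    rows = []
    for gi in range(10):
        sel = g == gi
        if not sel.any():
            continue
        rows.append({"decile": gi + 1, "n": int(sel.sum()),
                     "mean_predicted": float(p[sel].mean()),
                     "observed_mortality": float(y[sel].mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort-characteristics tests

def two_sample_t(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, int, float]:
    """Pooled-variance unpaired t test from summary statistics."""
    for n in (n1, n2):
        if n < 2:
            raise ValueError("each group needs n >= 2")
    for sd in (sd1, sd2):
        if sd <= 0:
            raise ValueError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


def two_sample_t_raw(x1, x2) -> tuple[float, int, float]:
    """Pooled-variance unpaired t test from raw data."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    res = sps.ttest_ind(x1, x2, equal_var=True)
    return float(res.statistic), len(x1) + len(x2) - 2, float(res.pvalue)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on [[a,b],[c,d]]."""
    t = np.array([[a, b], [c, d]], dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p (hypergeometric enumeration, via scipy)."""
    t = np.array([[a, b], [c, d]])
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(t)[1])
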