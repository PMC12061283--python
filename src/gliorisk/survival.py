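"""Marker-based risk score, optimal-cutpoint stratification and survival fits.

The risk score of a sample is the mean of the z-scored log expression of
the cluster marker genes (z-scoring per gene equalizes gene scales before
averaging).  Samples are split into high/low risk at the score cutpoint
minimizing the log-rank p-value among splits that keep both groups within
the 10th-90th score percentiles; the stratification is then characterized
by Kaplan-Meier curves, the log-rank test, a multivariate Cox
proportional-hazards model with collinearity diagnostics (VIF/tolerance),
and the ROC AUC of the score against vital status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

__all__ = [
    "RiskModel",
    "compute_risk_score",
    "km_estimate",
    "logrank_test",
    "optimal_cutpoint",
    "cox_fit",
    "collinearity_check",
    "roc_auc",
    "RiskStratifier",
]


def compute_risk_score(bulk: pd.DataFrame, markers: list[str]) -> pd.Series:
    """Mean of per-gene z-scored log expression of the marker genes.

    Each marker's log1p expression is z-scored across samples (population
    standard deviation); the per-sample score is the average of the marker
    z-scores, re-standardized so the cohort score has mean 0 and unit
    variance.
    """
    missing = [g for g in markers if g not in bulk.columns]
    if missing:
        raise KeyError(f"marker gene(s) absent from the cohort: {missing}")
    z = np.zeros((len(bulk), len(markers)))
    for k, g in enumerate(markers):
        x = np.log1p(bulk[g].to_numpy(dtype=float))
        sd = x.std()
        if np.ptp(x) == 0 or sd == 0:
            raise ValueError(f"marker {g} has zero variance across samples")
        z[:, k] = (x - x.mean()) / sd
    score = z.mean(axis=1)
    score = (score - score.mean()) / score.std()
    return pd.Series(score, index=bulk.index, name="risk_score")


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a step function as a DataFrame with columns ``time`` and
    ``survival`` (one row per event time, starting from (0, 1)).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter().fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test (chi-square with 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {len(levels)}")
    if events.sum() == 0:
        return 0.0, 1.0
    a = group == levels[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, p


def optimal_cutpoint(
    score, times, events, lo: float = 0.10, hi: float = 0.90
) -> tuple[float, np.ndarray]:
    """Score cutpoint minimizing the log-rank p-value.

    Candidate cutpoints are the observed score values whose induced split
    (high = score > cutpoint) leaves both groups within the [lo, hi]
    quantile bounds of the cohort.  Returns the argmin cutpoint (ties go to
    the smaller value) and the high/low labels it induces.
    """
    score = np.asarray(score, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = score.size
    if n < 10:
        raise ValueError("need at least 10 samples for the cutpoint scan")
    if np.all(score == score[0]):
        raise ValueError("score is constant; no cutpoint exists")
    n_lo = int(np.ceil(lo * n))
    n_hi = int(np.floor(hi * n))
    best_p = np.inf
    best_cut = None
    candidates = np.unique(score)
    n_evaluated = 0
    for c in candidates:
        n_low = int((score <= c).sum())
        if n_low < n_lo or n_low > n_hi:
            continue
        n_evaluated += 1
        grp = np.where(score > c, "high", "low")
        _, p = logrank_test(times, events, grp)
        # candidates ascend, so on ties the smaller cutpoint is kept
        if p < best_p:
            best_p = p
            best_cut = float(c)
    if best_cut is None:
        raise ValueError("no candidate cutpoint satisfies the quantile bounds")
    groups = np.where(score > best_cut, "high", "low")
    optimal_cutpoint.last_n_candidates = n_evaluated  # diagnostic for reports
    return best_cut, groups


def cox_fit(covariates: pd.DataFrame, times, events) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    Returns one row per covariate with hazard ratio, Wald 95% CI and p.
    """
    covariates = covariates.astype(float)
    const = covariates.columns[covariates.std() == 0].tolist()
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    n_events = int(np.asarray(events).sum())
    if n_events < 5 * covariates.shape[1]:
        warnings.warn(
            f"only {n_events} events for {covariates.shape[1]} covariates; "
            "estimates may be unstable"
        )
    df = covariates.copy()
    df["time"] = np.asarray(times, dtype=float)
    df["event"] = np.asarray(events, dtype=int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    return pd.DataFrame(
        {
            "hr": np.exp(summary["coef"]),
            "ci_low": np.exp(summary["coef lower 95%"]),
            "ci_high": np.exp(summary["coef upper 95%"]),
            "p": summary["p"],
        },
        index=summary.index,
    )


def collinearity_check(covariates: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor and tolerance per covariate.

    VIF_j = 1/(1 - R^2_j) from an OLS regression (with intercept) of
    covariate j on the remaining covariates; tolerance = 1/VIF.  Perfectly
    collinear covariates get infinite VIF and are flagged.
    """
    covariates = covariates.astype(float)
    if covariates.shape[1] < 2:
        raise ValueError("need at least two covariates")
    const = covariates.columns[covariates.std() == 0].tolist()
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    X = covariates.to_numpy()
    out = []
    for j in range(X.shape[1]):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            vif, tol, flag = np.inf, 0.0, True
        else:
            vif = 1.0 / (1.0 - r2)
            tol = 1.0 - r2
            flag = False
        out.append({"vif": vif, "tolerance": tol, "collinear": flag})
    return pd.DataFrame(out, index=covariates.columns)


def roc_auc(score, status) -> float:
    """AUC of the score against a binary status (ties count half).

    Equals the rank-sum (Mann-Whitney) estimator: the probability that a
    random event sample scores above a random non-event sample.
    """
    status = np.asarray(status, dtype=int)
    if len(np.unique(status)) < 2:
        raise ValueError("both statuses must be present")
    return float(roc_auc_score(status, np.asarray(score, dtype=float)))


@dataclass
class RiskModel:
    """Fitted risk stratification: scores, cutpoint and survival summary."""

    marker_genes: list[str]
    score: pd.Series
    cutpoint: float
    group: pd.Series
    km_curves: dict[str, pd.DataFrame]
    logrank_stat: float
    logrank_p: float
    cox: pd.DataFrame | None = None
    vif: pd.DataFrame | None = None
    auc: float = float("nan")
    n_cutpoint_candidates: int = 0


class RiskStratifier(BaseEstimator):
    """Marker-gene risk score with optimal-cutpoint survival stratification.

    ``fit`` computes per-sample scores from the marker genes, scans for the
    optimal log-rank cutpoint, and fits KM curves, the log-rank test, the
    ROC AUC against event status and (when extra covariates are supplied) a
    multivariate Cox model with VIF/tolerance diagnostics.  ``predict``
    labels new samples high/low against the fitted cutpoint.
    """

    def __init__(self, markers: list[str], lo: float = 0.10, hi: float = 0.90):
        self.markers = markers
        self.lo = lo
        self.hi = hi

    def fit(
        self,
        bulk: pd.DataFrame,
        clinical: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
    ) -> "RiskStratifier":
        score = compute_risk_score(bulk, list(self.markers))
        times = clinical["time"].to_numpy(dtype=float)
        events = clinical["event"].to_numpy(dtype=int)
        cut, groups = optimal_cutpoint(
            score.to_numpy(), times, events, lo=self.lo, hi=self.hi
        )
        n_candidates = getattr(optimal_cutpoint, "last_n_candidates", 0)
        stat, p = logrank_test(times, events, groups)
        km = {
            g: km_estimate(times[groups == g], events[groups == g])
            for g in ("high", "low")
        }
        cox = vif = None
        if covariates is not None:
            table = covariates.copy()
            table.insert(0, "risk_score", score)
            cox = cox_fit(table, times, events)
            vif = collinearity_check(table)
        auc = roc_auc(score.to_numpy(), events)
        self.model_ = RiskModel(
            marker_genes=list(self.markers),
            score=score,
            cutpoint=cut,
            group=pd.Series(groups, index=score.index, name="risk_group"),
            km_curves=km,
            logrank_stat=stat,
            logrank_p=p,
            cox=cox,
            vif=vif,
            auc=auc,
            n_cutpoint_candidates=n_candidates,
        )
        return self

    def predict(self, bulk: pd.DataFrame) -> pd.Series:
        score = compute_risk_score(bulk, list(self.markers))
        return pd.Series(
            np.where(score > self.model_.cutpoint, "high", "low"),
            index=bulk.index,
            name="risk_group",
        )
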