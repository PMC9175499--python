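"""Lung-transplant-free survival analysis.

The endpoint is composite: time from surgical biopsy to the first of death or
lung transplantation (LTx), in months; subjects alive at last follow-up are
censored.  The module builds survival records from the cohort table, estimates
Kaplan–Meier curves with Greenwood standard errors, compares groups with the
log-rank test, and fits Cox proportional-hazards models.

The Cox partial likelihood is maximised by Newton–Raphson with the Efron tie
correction by default (Breslow available for cross-checking).  Convergence is
declared when the maximum absolute score component falls below 1e-8, within at
most 50 iterations; monotone likelihood (perfect separation) is flagged via
``converged=False`` rather than silently returning a finite estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import DataError, UndefinedMetricError

log = logging.getLogger(__name__)

EVENT_STATUSES = {"died", "transplanted"}

#: Covariates offered to the multivariate model; p16_high and antifibrotic are
#: the primary exposures, the rest are screening candidates.
DEFAULT_COVARIATES = ["p16_high", "antifibrotic", "age", "sex", "bmi", "fvc_pct", "dlco_pct"]


def ltx_free_records(cohort: pd.DataFrame) -> pd.DataFrame:
    """Build (time, event) survival records under the death-or-LTx endpoint.

    ``event`` is True when status is died or transplanted; alive subjects are
    censored at their follow-up time.  Records with non-positive follow-up are
    rejected with a log entry.
    """
    records = []
    for _, row in cohort.iterrows():
        t = float(row["followup_months"])
        if not t > 0:
            log.warning(
                "patient %s: non-positive follow-up (%s months); record rejected",
                row.get("patient_id", "?"),
                t,
            )
            continue
        rec = {
            "patient_id": row.get("patient_id"),
            "time": t,
            "event": row["status"] in EVENT_STATUSES,
        }
        if "density" in row and "p16_class" in row:
            rec["p16_high"] = float(row["p16_class"] == "high")
        if "treatment" in row:
            rec["antifibrotic"] = float(row["treatment"] == "antifibrotic")
        for cov in ("age", "bmi", "fvc_pct", "dlco_pct"):
            if cov in row:
                rec[cov] = row[cov]
        if "sex" in row:
            rec["sex"] = float(row["sex"] == "M")
        records.append(rec)
    return pd.DataFrame(records)


@dataclass
class KMCurve:
    """Product-limit survival estimate with Greenwood standard errors."""

    event_times: np.ndarray  # distinct observed times (events and censorings)
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
                "se": self.greenwood_se,
            }
        )


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier estimate (ties at a time processed together)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise DataError("km_estimate needs at least one record")
    kmf = KaplanMeierFitter().fit(time, event_observed=event)
    # drop the t=0 anchor row lifelines inserts
    table = kmf.event_table[kmf.event_table.index > 0]
    times = table.index.to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=int)
    d = table["observed"].to_numpy(dtype=int)
    surv = np.asarray(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in times]
    )
    # Greenwood: var S(t) = S(t)^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(at_risk > d, d / (at_risk * (at_risk - d)), 0.0)
    se = surv * np.sqrt(np.cumsum(incr))
    return KMCurve(
        event_times=times, survival=surv, at_risk=at_risk, n_events=d, greenwood_se=se
    )


@dataclass
class LogrankResult:
    statistic: float
    p_value: float


def logrank_test(time_a, event_a, time_b, event_b) -> LogrankResult:
    """Two-group log-rank test (1 df chi-square)."""
    time_a = np.asarray(time_a, dtype=float)
    time_b = np.asarray(time_b, dtype=float)
    event_a = np.asarray(event_a, dtype=bool)
    event_b = np.asarray(event_b, dtype=bool)
    if time_a.size == 0 or time_b.size == 0:
        raise DataError("both groups must be non-empty")
    if event_a.sum() + event_b.sum() == 0:
        raise UndefinedMetricError("log-rank test undefined with zero events")
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return LogrankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


@dataclass
class CoxFit:
    coefficients: dict
    hazard_ratios: dict
    standard_errors: dict
    wald_ci_95: dict
    p_values: dict
    log_partial_likelihood: float
    n_events: int
    converged: bool
    n_iterations: int
    covariates: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.covariates:
            rows.append(
                {
                    "covariate": c,
                    "coef": self.coefficients[c],
                    "hazard_ratio": self.hazard_ratios[c],
                    "se": self.standard_errors[c],
                    "ci_low": self.wald_ci_95[c][0],
                    "ci_high": self.wald_ci_95[c][1],
                    "p": self.p_values[c],
                }
            )
        return pd.DataFrame(rows)


def _partial_loglik_parts(beta, X, time, event, ties):
    """Log partial likelihood, score and information (Efron or Breslow ties).

    Arrays must be sorted by ascending time.  Returns (loglik, grad, info).
    """
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = w[:, None, None] * (X[:, :, None] * X[:, None, :])
    # risk-set sums: subjects with time >= t_i  -> reverse cumulative sums
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        dead = np.arange(i, j)[event[i:j]]
        d = dead.size
        if d > 0:
            sum_eta = eta[dead].sum()
            sum_x = X[dead].sum(axis=0)
            wD0 = w[dead].sum()
            wD1 = wX[dead].sum(axis=0)
            wD2 = wXX[dead].sum(axis=0)
            loglik += sum_eta
            grad += sum_x
            for ell in range(d):
                frac = ell / d if ties == "efron" else 0.0
                phi0 = S0[i] - frac * wD0
                phi1 = S1[i] - frac * wD1
                phi2 = S2[i] - frac * wD2
                loglik -= np.log(phi0)
                grad -= phi1 / phi0
                info += phi2 / phi0 - np.outer(phi1, phi1) / phi0**2
        i = j
    return loglik, grad, info


def cox_fit(
    data: pd.DataFrame,
    covariate_names: list[str],
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    `data` needs columns ``time`` (months, > 0) and ``event`` (bool) plus the
    requested covariates.  Missing covariate values are a hard error, as is a
    constant covariate (named in the message).  Monotone likelihood is flagged
    through ``converged=False``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    for col in ["time", "event", *covariate_names]:
        if col not in data.columns:
            raise DataError(f"survival data lacks column {col!r}")
    sub = data[["time", "event", *covariate_names]]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise DataError(f"missing values in survival model columns: {bad}")
    time = sub["time"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=bool)
    if event.sum() < 2:
        raise DataError("cox_fit requires at least 2 events")
    X = sub[covariate_names].to_numpy(dtype=float)
    for k, name in enumerate(covariate_names):
        if np.ptp(X[:, k]) == 0:
            raise DataError(f"covariate {name!r} is constant")

    order = np.argsort(time, kind="stable")
    time, event, X = time[order], event[order], X[order]
    # center covariates for numerical stability; slopes are unaffected
    center = X.mean(axis=0)
    Xc = X - center

    p = len(covariate_names)
    beta = np.zeros(p)
    loglik, grad, info = _partial_loglik_parts(beta, Xc, time, event, ties)
    converged = False
    it = 0
    slack = 1e-10 * max(1.0, abs(loglik))  # ascent check robust to rounding
    while it < max_iter:
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        it += 1
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving to guarantee ascent
        for _ in range(30):
            cand = beta + step
            cand_ll, cand_grad, cand_info = _partial_loglik_parts(
                cand, Xc, time, event, ties
            )
            if cand_ll >= loglik - slack:
                break
            step = step / 2.0
        beta, loglik, grad, info = cand, cand_ll, cand_grad, cand_info
    if np.max(np.abs(beta)) > 10:
        converged = False  # monotone likelihood / perfect separation
        log.warning("cox_fit: |beta| exploded; likely perfect separation")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    names = list(covariate_names)
    return CoxFit(
        coefficients=dict(zip(names, beta.tolist())),
        hazard_ratios=dict(zip(names, np.exp(beta).tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        wald_ci_95={
            n_: (float(np.exp(b - 1.96 * s)), float(np.exp(b + 1.96 * s)))
            for n_, b, s in zip(names, beta, se)
        },
        p_values=dict(zip(names, pvals.tolist())),
        log_partial_likelihood=float(loglik),
        n_events=int(event.sum()),
        converged=converged,
        n_iterations=it,
        covariates=names,
    )


def cox_partial_loglik(data: pd.DataFrame, covariate_names, beta, ties: str = "efron") -> float:
    """Log partial likelihood at an arbitrary coefficient vector.

    Exposed so that fits can be checked against direct likelihood evaluation.
    """
    sub = data[["time", "event", *covariate_names]]
    time = sub["time"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=bool)
    X = sub[covariate_names].to_numpy(dtype=float)
    order = np.argsort(time, kind="stable")
    ll, _, _ = _partial_loglik_parts(
        np.asarray(beta, dtype=float), X[order], time[order], event[order], ties
    )
    return float(ll)
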