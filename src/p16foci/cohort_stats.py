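"""Cohort-level statistics: descriptive summaries, diagnostic performance of
p16 scoring against the multidisciplinary-discussion (MDD) diagnosis, the HRCT
visual fibrosis score, and ROC-based cutoff derivation.

The cohort is a pandas DataFrame with one row per subject, read/written as TSV
with lowercase enum tokens and empty cells for missing values (see
:func:`read_cohort`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError, UndefinedMetricError

DIAGNOSES = ["IPF", "NSIP", "unclassifiable", "chronic_HP", "smoking_related"]

#: Continuous cohort fields summarised as mean ± SD.
CONTINUOUS_FIELDS = [
    "age",
    "bmi",
    "pack_years",
    "fvc_pct",
    "tlc_pct",
    "dlco_pct",
    "hrct_score_pct",
    "followup_months",
    "density",
]
#: Categorical cohort fields summarised as n (%).
CATEGORICAL_FIELDS = ["diagnosis", "sex", "p16_class", "hrct_pattern", "treatment", "status"]

COHORT_COLUMNS = [
    "patient_id",
    "diagnosis",
    "density",
    "p16_class",
    "age",
    "sex",
    "bmi",
    "pack_years",
    "fvc_pct",
    "tlc_pct",
    "dlco_pct",
    "hrct_pattern",
    "hrct_score_pct",
    "treatment",
    "followup_months",
    "status",
]


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV (one header row, PatientRecord field names)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("patient_id", "diagnosis") if c not in df.columns]
    if missing:
        raise DataError(f"cohort table lacks required column(s): {missing}")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise UndefinedMetricError("sensitivity undefined: no truth-positive subjects")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise UndefinedMetricError("specificity undefined: no truth-negative subjects")
        return self.tn / (self.tn + self.fp)


@dataclass
class DiagnosticPerformance:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]


def _as_bool_series(rule, cohort: pd.DataFrame) -> pd.Series:
    if callable(rule):
        return cohort.apply(rule, axis=1).astype(bool)
    return pd.Series(rule, index=cohort.index).astype(bool)


def diagnostic_performance(cohort: pd.DataFrame, predictor, truth) -> DiagnosticPerformance:
    """Sensitivity/specificity of a predictor rule against a truth rule.

    `predictor` and `truth` are either callables mapping a cohort row to bool
    or boolean array-likes aligned with the cohort.  Confidence intervals are
    exact (Clopper–Pearson) binomial 95% intervals.
    """
    if len(cohort) == 0:
        raise DataError("empty cohort")
    pred = _as_bool_series(predictor, cohort)
    tru = _as_bool_series(truth, cohort)
    counts = ConfusionCounts(
        tp=int((pred & tru).sum()),
        fp=int((pred & ~tru).sum()),
        tn=int((~pred & ~tru).sum()),
        fn=int((~pred & tru).sum()),
    )
    sens = counts.sensitivity
    spec = counts.specificity
    sens_ci = proportion_confint(counts.tp, counts.tp + counts.fn, alpha=0.05, method="beta")
    spec_ci = proportion_confint(counts.tn, counts.tn + counts.fp, alpha=0.05, method="beta")
    return DiagnosticPerformance(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
    )


def hrct_score(grades, n_scans: int = 4) -> float:
    """HRCT visual fibrosis score as a percent of the maximum.

    Each of the `n_scans` scan levels (aortic arch, bronchus intermedius,
    pulmonary veins, lowest scan) is graded 0–4 per hemithorax for extent of
    fibrosis (0 = no lesions; 1–4 = 0–25 / 25–50 / 50–75 / 75–100% extent).
    The score is 100 × (sum of grades) / (8 × n_scans).
    """
    grades = np.asarray(grades)
    if grades.size != 2 * n_scans:
        raise DataError(f"expected {2 * n_scans} grades (2 per scan level), got {grades.size}")
    if not np.all(np.isin(grades, [0, 1, 2, 3, 4])):
        raise DataError(f"grades must be integers in 0..4, got {sorted(set(grades.tolist()))}")
    return 100.0 * float(grades.sum()) / (8.0 * n_scans)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    best_cutoff: float
    best_accuracy: float


def roc_curve(values, events) -> ROCResult:
    """ROC analysis of a continuous marker against a binary outcome.

    Thresholds are midpoints between consecutive distinct observed values plus
    ±inf sentinels; a subject is called positive when value > threshold.  The
    AUC is the Mann–Whitney concordance (ties scored ½).  ``best_cutoff``
    maximises sensitivity + specificity, ties broken toward the smallest
    threshold (the most inclusive rule).
    """
    values = np.asarray(values, dtype=float)
    events = np.asarray(events, dtype=bool)
    if values.shape != events.shape or values.ndim != 1:
        raise DataError("values and events must be equal-length 1-D arrays")
    if not np.all(np.isfinite(values)):
        raise DataError("marker values must be finite")
    n_pos = int(events.sum())
    n_neg = int((~events).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("degenerate ROC: only one outcome class present")

    distinct = np.unique(values)
    thresholds = np.concatenate(
        ([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf])
    )
    pos = values[events]
    neg = values[~events]
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])

    # AUC by the Mann–Whitney U identity on midranks
    ranks = stats.rankdata(values)
    auc = (ranks[events].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    youden = sens + spec
    best = int(np.argmax(youden))  # first (= smallest threshold) among ties
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        best_cutoff=float(thresholds[best]),
        best_accuracy=float(youden[best]),
    )


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary: mean ± SD for continuous fields, n (%) for
    categorical fields.  Missing values are excluded pairwise; the non-missing
    count is reported per field.  A single observation reports SD 0.
    """
    if len(cohort) == 0:
        raise DataError("empty cohort")
    rows = []
    for col in CONTINUOUS_FIELDS:
        if col not in cohort.columns:
            continue
        vals = pd.to_numeric(cohort[col], errors="coerce").dropna()
        if len(vals) == 0:
            continue
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "field": col,
                "level": "",
                "n": int(len(vals)),
                "value": f"{vals.mean():.1f} ± {sd:.1f}",
                "mean": float(vals.mean()),
                "sd": sd,
            }
        )
    for col in CATEGORICAL_FIELDS:
        if col not in cohort.columns:
            continue
        series = cohort[col].dropna()
        total = len(series)
        if total == 0:
            continue
        for level, n in series.value_counts().items():
            rows.append(
                {
                    "field": col,
                    "level": str(level),
                    "n": int(n),
                    "value": f"{n} ({round(100 * n / total)}%)",
                    "mean": np.nan,
                    "sd": np.nan,
                }
            )
    return pd.DataFrame(rows)


def outcome_incidence(cohort: pd.DataFrame) -> dict:
    """Death-or-transplant and death incidences as nearest-integer percents."""
    status = cohort["status"].dropna()
    n = len(status)
    if n == 0:
        raise DataError("no outcome data")
    died = int((status == "died").sum())
    ltx = int((status == "transplanted").sum())
    return {
        "n": n,
        "n_died": died,
        "n_transplanted": ltx,
        "n_alive": n - died - ltx,
        "combined_death_or_ltx_pct": round(100.0 * (died + ltx) / n),
        "mortality_pct": round(100.0 * died / n),
    }


def p16_crosstab(cohort: pd.DataFrame) -> pd.DataFrame:
    """Diagnosis × p16-class cross-tabulation (counts with row percents)."""
    tab = pd.crosstab(cohort["diagnosis"], cohort["p16_class"])
    for cls in ("low", "high"):
        if cls not in tab.columns:
            tab[cls] = 0
    tab = tab[["low", "high"]]
    return tab.reindex([d for d in DIAGNOSES if d in tab.index])
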