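"""Treatment-concordance outcome analysis for CUP cohorts.

Whether a patient's first-line treatment was concordant with the
model-predicted tumor origin is the exposure; overall survival is the
outcome.  The module provides Kaplan-Meier estimation with medians and
log-log confidence intervals, log-rank tests, multivariate Cox
proportional-hazards regression with optional bidirectional AIC-stepwise
selection (the concordance term is forced to stay — it is the reported
exposure), RECIST response tabulation, and the Karnofsky functional-score
comparison with Bonferroni correction across timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times
from scipy import stats

from .errors import ConvergenceError, DataError, ParameterError

REQUIRED_COLUMNS = ("time", "event")

# Column aliases so externally supplied tables (spreadsheet exports) map onto
# the module's schema without editing the data.
DEFAULT_ALIASES = {
    "time": ("time", "os_months", "overall_survival_months", "survival_time"),
    "event": ("event", "death", "died", "status"),
    "concordance": ("concordance", "concordant_group", "treatment_concordance"),
    "response": ("response", "recist", "best_response"),
}


@dataclass
class SurvivalCohort:
    """Per-patient survival table: time (months), event (1=death), covariates."""

    table: pd.DataFrame

    def __post_init__(self):
        for col in REQUIRED_COLUMNS:
            if col not in self.table.columns:
                raise DataError(f"cohort table missing required column {col!r}")
        if (self.table["time"] < 0).any():
            raise DataError("survival times must be non-negative")
        if not set(self.table["event"].unique()) <= {0, 1}:
            raise DataError("event flag must be binary (1=death, 0=censored)")

    @classmethod
    def from_table(cls, df: pd.DataFrame, aliases: Optional[Dict] = None) -> "SurvivalCohort":
        amap = dict(DEFAULT_ALIASES)
        if aliases:
            amap.update(aliases)
        renames = {}
        lower = {c.lower(): c for c in df.columns}
        for canon, options in amap.items():
            for opt in options:
                if opt in lower and canon not in df.columns:
                    renames[lower[opt]] = canon
                    break
        return cls(df.rename(columns=renames))

    def subset(self, mask) -> "SurvivalCohort":
        return SurvivalCohort(self.table.loc[mask].reset_index(drop=True))

    def __len__(self):
        return len(self.table)


@dataclass
class KMResult:
    times: np.ndarray
    survival: np.ndarray
    median: float               # inf when not reached
    median_ci: tuple
    n: int
    events: int


def km_estimate(cohort, group: Optional[str] = None, value=None) -> KMResult:
    """Product-limit survival curve with median and 95% CI.

    The median is the earliest time with S(t) <= 0.5; with no events it is
    reported as not reached (inf).  The curve CI uses the log-log (Greenwood
    exponential) transform, from which the median CI is read off.
    """
    df = cohort.table if isinstance(cohort, SurvivalCohort) else pd.DataFrame(cohort)
    if group is not None:
        df = df[df[group] == value]
    if len(df) == 0:
        raise DataError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    median = float(kmf.median_survival_time_)
    ci_df = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
    sf = kmf.survival_function_
    return KMResult(times=sf.index.to_numpy(), survival=sf.iloc[:, 0].to_numpy(),
                    median=median, median_ci=(lo, hi),
                    n=len(df), events=int(df["event"].sum()))


def logrank_test(group_a, group_b) -> dict:
    """Two-sided log-rank chi-square test (1 df) between two survival groups."""
    a = group_a.table if isinstance(group_a, SurvivalCohort) else pd.DataFrame(group_a)
    b = group_b.table if isinstance(group_b, SurvivalCohort) else pd.DataFrame(group_b)
    if len(a) == 0 or len(b) == 0:
        raise DataError("both groups must be non-empty")
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return {"statistic": float(res.test_statistic), "p": float(res.p_value)}


@dataclass
class CoxResult:
    summary: pd.DataFrame               # coef, HR, CI bounds, p per term
    aic: float
    selected: Sequence[str]
    full_summary: pd.DataFrame = None   # no-selection model, always emitted
    separation_flags: list = field(default_factory=list)


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    X = df[list(covariates)].copy()
    X = pd.get_dummies(X, drop_first=True, dtype=float)
    return X


def _fit_cox(df: pd.DataFrame, cols: Sequence[str]) -> CoxPHFitter:
    data = pd.concat([df[["time", "event"]].reset_index(drop=True),
                      pd.DataFrame(df[list(cols)]).reset_index(drop=True)], axis=1)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError-like exceptions
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    return cph


def _summarize(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    return pd.DataFrame({
        "coef": s["coef"], "hr": s["exp(coef)"],
        "hr_lower": s["exp(coef) lower 95%"], "hr_upper": s["exp(coef) upper 95%"],
        "p": s["p"],
    })


def cox_multivariate(cohort, covariates: Sequence[str], stepwise: bool = False,
                     forced: Sequence[str] = ()) -> CoxResult:
    """Multivariate Cox proportional-hazards regression (partial likelihood,
    Efron tie handling; Wald CIs; HR = exp(coef)).

    With ``stepwise=True``, bidirectional AIC-based selection runs over the
    dummy-coded terms; any term whose name starts with a ``forced`` prefix is
    kept in the model throughout.  The full (no-selection) model is always
    returned alongside.  Quasi-separated covariates (|coef| > 15) are flagged
    rather than silently reported.
    """
    df = cohort.table if isinstance(cohort, SurvivalCohort) else pd.DataFrame(cohort)
    X = _design(df, covariates)
    if df["event"].sum() < X.shape[1]:
        raise DataError("fewer events than covariates")
    work = pd.concat([df[["time", "event"]].reset_index(drop=True),
                      X.reset_index(drop=True)], axis=1)
    all_terms = list(X.columns)
    full = _fit_cox(work, all_terms)
    full_summary = _summarize(full)

    def is_forced(term):
        return any(term == f or term.startswith(f"{f}_") for f in forced)

    if not stepwise:
        flags = [t for t, c in zip(full_summary.index, full_summary["coef"])
                 if abs(c) > 15]
        return CoxResult(summary=full_summary, aic=float(full.AIC_partial_),
                         selected=all_terms, full_summary=full_summary,
                         separation_flags=flags)

    current = list(all_terms)
    best_aic = float(full.AIC_partial_)
    improved = True
    while improved:
        improved = False
        candidates = []
        for term in current:
            if is_forced(term):
                continue
            candidates.append([t for t in current if t != term])
        for term in all_terms:
            if term not in current:
                candidates.append(current + [term])
        for cols in candidates:
            if not cols:
                continue
            try:
                fit = _fit_cox(work, cols)
            except ConvergenceError:
                continue
            if fit.AIC_partial_ < best_aic - 1e-9:
                best_aic = float(fit.AIC_partial_)
                current = list(cols)
                improved = True
    final = _fit_cox(work, current)
    summary = _summarize(final)
    flags = [t for t, c in zip(summary.index, summary["coef"]) if abs(c) > 15]
    return CoxResult(summary=summary, aic=float(final.AIC_partial_), selected=current,
                     full_summary=full_summary, separation_flags=flags)


def response_tabulate(cohort, subgroup: Optional[dict] = None,
                      response_col: str = "response") -> pd.DataFrame:
    """Counts and percentages (one decimal) of PR/SD/PD with denominators."""
    df = cohort.table if isinstance(cohort, SurvivalCohort) else pd.DataFrame(cohort)
    if subgroup:
        for col, val in subgroup.items():
            df = df[df[col] == val]
    df = df[df[response_col].notna()]
    if len(df) == 0:
        raise DataError("no rows with a response category after filtering")
    denom = len(df)
    rows = []
    for cat in ("PR", "SD", "PD"):
        cnt = int((df[response_col] == cat).sum())
        rows.append({"response": cat, "count": cnt, "denominator": denom,
                     "percent": round(100.0 * cnt / denom, 1)})
    return pd.DataFrame(rows)


def karnofsky_compare(cohort, group_col: str = "concordance",
                      timepoint_cols: Sequence[str] = ("karnofsky_admission",
                                                       "karnofsky_3_6m")) -> pd.DataFrame:
    """Two-sided two-sample t-tests of the functional score between groups at
    each timepoint, Bonferroni-corrected across the timepoints."""
    df = cohort.table if isinstance(cohort, SurvivalCohort) else pd.DataFrame(cohort)
    groups = sorted(df[group_col].unique())
    if len(groups) != 2:
        raise DataError("Karnofsky comparison requires exactly two groups")
    rows = []
    m = len(timepoint_cols)
    for col in timepoint_cols:
        a = df.loc[df[group_col] == groups[0], col].dropna()
        b = df.loc[df[group_col] == groups[1], col].dropna()
        t, p = stats.ttest_ind(a, b)
        rows.append({"timepoint": col, f"mean_{groups[0]}": a.mean(),
                     f"mean_{groups[1]}": b.mean(), "t": float(t),
                     "p": float(p), "p_bonferroni": float(min(1.0, p * m))})
    return pd.DataFrame(rows)
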