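"""Univariate survival screening: Cox rows, BH-FDR, K–M summaries.

Each clinical covariate and each miRNA is screened one at a time against a
right-censored endpoint with a single-covariate Cox model (Efron tie
handling, Wald confidence intervals and p-values).  Categorical covariates
expand to dummy rows against a stated reference level (stage I, female,
never-smoker, no treatment).  The Benjamini–Hochberg step-up procedure is
applied to the miRNA p-values only, never to clinical covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .datatypes import ExpressionMatrix, coarse_stage, endpoint_columns

#: reference level used when a categorical covariate expands to dummies
REFERENCE_LEVELS = {
    "stage": "I",
    "gender": "female",
    "smoking": "never",
    "chemo": False,
    "radio": False,
}


@dataclass
class UnivariateCoxRow:
    """One term of a univariate Cox fit (a dummy level or a numeric slope)."""

    term: str
    beta: float
    se: float
    hazard_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float
    n: int
    n_events: int
    flag: str = ""      # "" or "nonconvergent"


def _fit_cox_frame(df: pd.DataFrame, time_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # tight Newton precision so small-sample fits agree with an
        # independent maximization of the partial likelihood to < 1e-4
        cph.fit(df, duration_col=time_col, event_col=event_col,
                fit_options={"precision": 1e-9})
    return cph


def fit_univariate_cox(times: np.ndarray, events: np.ndarray,
                       covariate: pd.Series | np.ndarray,
                       name: str = "x") -> list[UnivariateCoxRow]:
    """Single-covariate Cox regression (Efron ties, Wald inference).

    Numeric covariates yield one row; categorical covariates yield one row
    per non-reference level.  A monotone-likelihood (non-convergent) fit is
    returned as a flagged row with infinite CI bounds rather than raising.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() == 0:
        raise ValueError("no events; univariate Cox is undefined")
    cov = pd.Series(covariate).reset_index(drop=True)
    cov.name = name

    keep = cov.notna().to_numpy()
    times, events, cov = times[keep], events[keep], cov[keep].reset_index(drop=True)
    n, n_events = len(times), int(events.sum())

    if cov.dtype == object or isinstance(cov.dtype, pd.CategoricalDtype) or cov.dtype == bool:
        levels = list(pd.unique(cov))
        ref = REFERENCE_LEVELS.get(name)
        if ref is None or ref not in levels:
            ref = sorted(levels, key=str)[0]
        others = [lv for lv in levels if lv != ref]
        if not others:
            raise ValueError(f"covariate {name!r} is constant")
        design = pd.DataFrame(
            {f"{name}={lv}": (cov == lv).astype(float) for lv in others})
        terms = list(design.columns)
    else:
        if float(np.nanstd(cov.to_numpy(dtype=float))) == 0.0:
            raise ValueError(f"covariate {name!r} is constant")
        design = pd.DataFrame({name: cov.to_numpy(dtype=float)})
        terms = [name]

    df = design.copy()
    df["_time"], df["_event"] = times, events.astype(int)
    try:
        cph = _fit_cox_frame(df, "_time", "_event")
    except ConvergenceError:
        return [UnivariateCoxRow(term=t, beta=np.nan, se=np.inf,
                                 hazard_ratio=np.nan, ci95_low=0.0,
                                 ci95_high=np.inf, p_value=np.nan,
                                 n=n, n_events=n_events, flag="nonconvergent")
                for t in terms]
    rows = []
    for t in terms:
        beta = float(cph.params_[t])
        se = float(cph.standard_errors_[t])
        flag = ""
        if not np.isfinite(se) or se > 50:
            flag = "nonconvergent"
        with np.errstate(over="ignore"):
            rows.append(UnivariateCoxRow(
                term=t, beta=beta, se=se, hazard_ratio=float(np.exp(beta)),
                ci95_low=float(np.exp(beta - 1.959963984540054 * se)),
                ci95_high=float(np.exp(beta + 1.959963984540054 * se)),
                p_value=float(cph.summary.loc[t, "p"]), n=n, n_events=n_events,
                flag=flag))
    return rows


def benjamini_hochberg(p_values: np.ndarray, delta: float = 0.05) -> pd.DataFrame:
    """Benjamini–Hochberg step-up procedure at FDR level ``delta``.

    Returns a frame aligned to the input order with the ascending rank j,
    the critical value (j/m)·delta, and the rejection decision: reject
    tests 1..j* where j* is the largest j with p_(j) ≤ (j/m)·delta.
    Ties keep input order (stable sort).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    critical_sorted = (np.arange(1, m + 1) / m) * delta
    passing = np.flatnonzero(sorted_p <= critical_sorted)
    j_star = (passing[-1] + 1) if passing.size else 0
    rejected_sorted = np.arange(m) < j_star

    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    critical = np.empty(m)
    critical[order] = critical_sorted
    rejected = np.empty(m, dtype=bool)
    rejected[order] = rejected_sorted
    return pd.DataFrame({"p_value": p, "bh_rank": rank,
                         "bh_critical": critical, "rejected": rejected})


def screen_mirnas(expr: ExpressionMatrix, clinical: pd.DataFrame,
                  endpoint: str, delta: float = 0.05) -> pd.DataFrame:
    """Univariate Cox per miRNA (−ΔCT scale) with BH-FDR annotation.

    Output mirrors the screening-table layout: term, HR, 95% CI, Wald p,
    BH rank and (j/m)·delta critical value, sorted by p ascending.
    """
    time_col, event_col = endpoint_columns(endpoint)
    cl = clinical.set_index("patient_id").loc[expr.patient_ids]
    times = cl[time_col].to_numpy(dtype=float)
    events = cl[event_col].to_numpy(dtype=bool)
    rows = []
    for gi, gid in enumerate(expr.mirna_ids):
        row = fit_univariate_cox(times, events, expr.value[:, gi], name=gid)[0]
        rows.append({"term": gid, "beta": row.beta, "HR": row.hazard_ratio,
                     "ci95_low": row.ci95_low, "ci95_high": row.ci95_high,
                     "p_value": row.p_value, "flag": row.flag})
    out = pd.DataFrame(rows)
    bh = benjamini_hochberg(out["p_value"].to_numpy(), delta=delta)
    out[["bh_rank", "bh_critical", "rejected"]] = bh[["bh_rank", "bh_critical", "rejected"]]
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def screen_clinical(clinical: pd.DataFrame, endpoint: str,
                    five_level_stage: bool = False) -> pd.DataFrame:
    """Univariate Cox rows for the clinical covariates (no FDR)."""
    time_col, event_col = endpoint_columns(endpoint)
    times = clinical[time_col].to_numpy(dtype=float)
    events = clinical[event_col].to_numpy(dtype=bool)
    stage = clinical["stage"] if five_level_stage else coarse_stage(clinical["stage"])
    covs = {
        "gender": clinical["gender"],
        "age_at_surgery": clinical["age_at_surgery"],
        "smoking": clinical["smoking"],
        "stage": stage,
        "chemo": clinical["chemo"],
        "radio": clinical["radio"],
    }
    rows = []
    for name, series in covs.items():
        try:
            fitted = fit_univariate_cox(times, events, series, name=name)
        except ValueError:
            continue
        for r in fitted:
            rows.append({"term": r.term, "beta": r.beta, "HR": r.hazard_ratio,
                         "ci95_low": r.ci95_low, "ci95_high": r.ci95_high,
                         "p_value": r.p_value, "flag": r.flag})
    return pd.DataFrame(rows)


@dataclass
class KMSummary:
    """Product-limit curves per group with medians, CIs and a log-rank test."""

    curves: dict[str, pd.DataFrame]          # time, survival, ci_low, ci_high
    medians: dict[str, tuple[float, float, float]]  # median, lo, hi (NaN = not reached)
    logrank_stat: float | None
    logrank_p: float | None


def km_summary(times: np.ndarray, events: np.ndarray,
               group: np.ndarray | None = None) -> KMSummary:
    """Kaplan–Meier curves with medians (log-log CIs) and a log-rank test.

    The median is the earliest time at which survival drops to 0.5 or
    below; if the curve never does, it is reported as NaN (not reached).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no subjects")
    if group is None:
        group = np.array(["all"] * len(times))
    group = np.asarray(group).astype(str)
    curves, medians = {}, {}
    for g in sorted(set(group)):
        sel = group == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        ci = kmf.confidence_interval_survival_function_
        curves[g] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
        })
        med = kmf.median_survival_time_
        med_ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])
        medians[g] = (float(med) if np.isfinite(med) else np.nan,
                      lo if np.isfinite(lo) else np.nan,
                      hi if np.isfinite(hi) else np.nan)
    if len(curves) > 1:
        lr = multivariate_logrank_test(times, group, events)
        stat, p = float(lr.test_statistic), float(lr.p_value)
    else:
        stat, p = None, None
    return KMSummary(curves=curves, medians=medians,
                     logrank_stat=stat, logrank_p=p)


def median_followup(times: np.ndarray, events: np.ndarray) -> float:
    """Median of times at risk restricted to censored patients.

    With an even count the mean-of-middle-two convention applies; with no
    censored patients the result is NaN (with a warning).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    censored = times[~events]
    if censored.size == 0:
        warnings.warn("no censored patients; median follow-up undefined")
        return float("nan")
    return float(np.median(censored))
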