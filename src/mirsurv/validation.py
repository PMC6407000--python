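"""Simon-style internal validation of the combined prognostic model.

Every patient receives a *cross-validated* prognostic index (PI): the
entire modelling procedure — miRNA standardization, elastic-net path,
inner K-fold lambda selection — is refit on the other n−1 patients, and
the held-out patient is scored by that model.  Nothing from the held-out
patient leaks into the fit that scores them.

On the cross-validated PIs the engine computes

* a median-split into high/low risk groups with K–M curves and the
  log-rank statistic (patients exactly at the median go to the low group);
* a cumulative-case / dynamic-control time-dependent ROC at a landmark
  ``t_star`` with inverse-probability-of-censoring weights from the K–M
  estimate of the censoring distribution, and its AUC;
* permutation p-values, always with the +1 convention
  ``p = (1 + #{perm ≥ obs}) / (B_ok + 1)``:
  - outcome shuffling (times/events permuted against all covariate rows,
    full pipeline rerun) for the log-rank statistic and for AUC vs 0.5;
  - miRNA-only reassignment (clinical/outcome correspondence intact) for
    the added predictive value of the miRNAs over the clinical-only model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import TAG_LOOCV, TAG_PERM_MIRNA, TAG_PERM_OUTCOME, child_rng, child_seed
from .datatypes import ExpressionMatrix, endpoint_columns
from .penalized import (DegenerateFitError, ModelConfig, PenalizedCoxFit,
                        fit_clinical_cox, fit_elastic_net_cox, prognostic_index)
from .screen import KMSummary, km_summary


@dataclass
class RocResult:
    """A time-dependent ROC curve at one landmark."""

    t_star: float
    curve: pd.DataFrame          # threshold, fpr, tpr
    auc: float


@dataclass
class ValidationReport:
    """Everything the validation engine measures for one model/endpoint."""

    endpoint: str
    cv_pi: np.ndarray
    risk_group: np.ndarray                   # "high"/"low"
    cv_km: KMSummary | None
    cv_logrank_stat: float
    p_logrank_perm: float | None
    roc_time: float
    cv_roc: pd.DataFrame | None
    cv_auc: float
    p_auc_vs_half: float | None
    p_added_value_logrank: float | None
    p_added_value_auc: float | None
    n_permutations: int
    clinical_only_logrank_stat: float | None = None
    clinical_only_auc: float | None = None
    n_failed_permutations: int = 0

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "cv_pi": self.cv_pi.tolist(),
            "risk_group": self.risk_group.tolist(),
            "cv_logrank_stat": self.cv_logrank_stat,
            "p_logrank_perm": self.p_logrank_perm,
            "roc_time": self.roc_time,
            "cv_auc": self.cv_auc,
            "p_auc_vs_half": self.p_auc_vs_half,
            "p_added_value_logrank": self.p_added_value_logrank,
            "p_added_value_auc": self.p_added_value_auc,
            "n_permutations": self.n_permutations,
            "clinical_only_logrank_stat": self.clinical_only_logrank_stat,
            "clinical_only_auc": self.clinical_only_auc,
            "n_failed_permutations": self.n_failed_permutations,
        }


def loocv_prognostic_indices(expr: ExpressionMatrix | None,
                             clinical: pd.DataFrame, endpoint: str,
                             model_config: ModelConfig | None = None,
                             seed: int = 0) -> np.ndarray:
    """Leave-one-out cross-validated prognostic indices.

    For patient i the full modelling procedure (including inner K-fold
    lambda selection, re-seeded deterministically from (seed, i)) is refit
    on the remaining patients; ``cv_pi[i]`` is the held-out patient's
    linear predictor.  A degenerate inner fit records NaN with a warning.
    ``expr=None`` scores the clinical-only model the same way.
    """
    model_config = model_config or ModelConfig()
    cl = clinical.reset_index(drop=True)
    n = len(cl)
    if n < 20:
        warnings.warn(f"LOOCV on only {n} patients; estimates will be noisy")
    cv_pi = np.full(n, np.nan)
    for i in range(n):
        rest = np.ones(n, dtype=bool)
        rest[i] = False
        cl_tr = cl.loc[rest].reset_index(drop=True)
        held = cl.loc[[i]].reset_index(drop=True)
        try:
            if expr is not None:
                expr_tr = ExpressionMatrix(
                    patient_ids=[expr.patient_ids[j] for j in np.flatnonzero(rest)],
                    mirna_ids=list(expr.mirna_ids),
                    value=expr.value[rest])
                fit = fit_elastic_net_cox(expr_tr, cl_tr, endpoint,
                                          config=model_config,
                                          seed=child_seed(seed, TAG_LOOCV, i))
                expr_held = ExpressionMatrix(
                    patient_ids=[expr.patient_ids[i]],
                    mirna_ids=list(expr.mirna_ids),
                    value=expr.value[[i]])
                cv_pi[i] = prognostic_index(fit, expr_held, held)[0]
            else:
                fit = fit_clinical_cox(cl_tr, endpoint,
                                       model_config.clinical_covariates)
                cv_pi[i] = prognostic_index(fit, None, held)[0]
        except (DegenerateFitError, ValueError, ArithmeticError) as exc:
            warnings.warn(f"LOOCV fit for patient {i} failed: {exc}")
    return cv_pi


def median_risk_groups(cv_pi: np.ndarray) -> np.ndarray:
    """Median split of the PIs: strictly above the median is high risk,
    at or below (ties and exact-median patients) is low risk."""
    cv_pi = np.asarray(cv_pi, dtype=float)
    ok = np.isfinite(cv_pi)
    if ok.sum() < 2 or np.nanstd(cv_pi) == 0.0:
        raise DegenerateFitError("cross-validated PIs are degenerate; "
                                 "cannot form risk groups")
    med = np.median(cv_pi[ok])
    group = np.where(cv_pi > med, "high", "low")
    group[~ok] = "NA"
    return group


def cv_km_and_logrank(cv_pi: np.ndarray, clinical: pd.DataFrame,
                      endpoint: str) -> tuple[np.ndarray, KMSummary, float]:
    """Median-split risk groups, their K–M curves and the log-rank statistic."""
    time_col, event_col = endpoint_columns(endpoint)
    group = median_risk_groups(cv_pi)
    ok = group != "NA"
    if len(set(group[ok])) < 2:
        raise DegenerateFitError(
            "median split produced a single risk group (majority of "
            "patients share the maximal prognostic index)")
    km = km_summary(clinical[time_col].to_numpy(dtype=float)[ok],
                    clinical[event_col].to_numpy(dtype=bool)[ok],
                    group[ok])
    return group, km, float(km.logrank_stat)


def _censoring_survival(times: np.ndarray, events: np.ndarray):
    """K–M estimate of the censoring distribution G(t); returns a step
    evaluator supporting right-continuous G(t) and left limits G(t−)."""
    from sksurv.nonparametric import kaplan_meier_estimator
    cens_times, cens_prob = kaplan_meier_estimator(~events.astype(bool), times)

    def G(t: np.ndarray, left: bool = False) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        side = "left" if left else "right"
        idx = np.searchsorted(cens_times, t, side=side)
        out = np.where(idx == 0, 1.0, cens_prob[np.clip(idx - 1, 0, None)])
        return out

    return G


def cv_time_dependent_roc(cv_pi: np.ndarray, times: np.ndarray,
                          events: np.ndarray, t_star: float) -> RocResult:
    """Cumulative/dynamic ROC at ``t_star`` with IPCW weights.

    Cases are patients with an observed event by ``t_star`` (weight
    1/G(T_i−)); controls are patients still event-free beyond ``t_star``
    (constant weight 1/G(t_star), which cancels).  The AUC is the weighted
    concordance of PI between cases and controls, ties counting 1/2 —
    identical to the trapezoid area under the weighted (FPR, TPR) curve.
    """
    cv_pi = np.asarray(cv_pi, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    ok = np.isfinite(cv_pi)
    cv_pi, times, events = cv_pi[ok], times[ok], events[ok]
    case = (times <= t_star) & events
    control = times > t_star
    if case.sum() == 0:
        raise ValueError(f"no events by t_star={t_star}")
    if control.sum() == 0:
        raise ValueError(f"no patients at risk beyond t_star={t_star}")
    G = _censoring_survival(times, events)
    w_case = 1.0 / G(times[case], left=True)
    if not np.all(np.isfinite(w_case)):
        raise ValueError("censoring-survival weight degenerate at a case time")
    pi_case, pi_ctrl = cv_pi[case], cv_pi[control]
    w_ctrl = np.ones(pi_ctrl.size)

    # weighted ROC curve over descending thresholds
    thresholds = np.unique(np.concatenate([pi_case, pi_ctrl]))[::-1]
    tpr = [(w_case * (pi_case > c).astype(float)).sum() / w_case.sum()
           for c in thresholds]
    fpr = [(w_ctrl * (pi_ctrl > c).astype(float)).sum() / w_ctrl.sum()
           for c in thresholds]
    curve = pd.DataFrame({
        "threshold": np.concatenate([[np.inf], thresholds, [-np.inf]]),
        "fpr": np.concatenate([[0.0], fpr, [1.0]]),
        "tpr": np.concatenate([[0.0], tpr, [1.0]]),
    })

    # weighted concordance (ties = 1/2)
    greater = pi_case[:, None] > pi_ctrl[None, :]
    equal = pi_case[:, None] == pi_ctrl[None, :]
    num = (w_case[:, None] * w_ctrl[None, :] * (greater + 0.5 * equal)).sum()
    auc = float(num / (w_case.sum() * w_ctrl.sum()))
    return RocResult(t_star=t_star, curve=curve, auc=auc)


def _pipeline_stats(expr: ExpressionMatrix | None, clinical: pd.DataFrame,
                    endpoint: str, model_config: ModelConfig, seed: int,
                    t_star: float) -> tuple[float, float, np.ndarray]:
    """Run LOOCV end to end; return (logrank stat, AUC, cv_pi)."""
    time_col, event_col = endpoint_columns(endpoint)
    cv_pi = loocv_prognostic_indices(expr, clinical, endpoint,
                                     model_config, seed)
    _, _, stat = cv_km_and_logrank(cv_pi, clinical, endpoint)
    roc = cv_time_dependent_roc(cv_pi,
                                clinical[time_col].to_numpy(dtype=float),
                                clinical[event_col].to_numpy(dtype=bool),
                                t_star)
    return stat, roc.auc, cv_pi


def _perm_pvalue(observed: float, permuted: list[float]) -> float:
    arr = np.asarray(permuted, dtype=float)
    return float((1 + (arr >= observed).sum()) / (arr.size + 1))


def permutation_test_logrank(expr: ExpressionMatrix, clinical: pd.DataFrame,
                             endpoint: str, B: int = 1000, seed: int = 0,
                             model_config: ModelConfig | None = None,
                             t_star: float = 24.0,
                             shuffle_stage_with_outcome: bool = False,
                             ) -> dict:
    """Outcome-shuffling permutation test of the cross-validated log-rank
    statistic (and, from the same reruns, of AUC vs 0.5).

    Each permutation shuffles the (time, event) pairs against the joint
    (miRNA, clinical) rows and reruns the full pipeline, LOOCV included.
    With ``shuffle_stage_with_outcome`` the stage column travels with the
    outcomes instead of staying with the miRNAs.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    model_config = model_config or ModelConfig()
    cl = clinical.reset_index(drop=True)
    time_col, event_col = endpoint_columns(endpoint)
    obs_stat, obs_auc, cv_pi = _pipeline_stats(expr, cl, endpoint,
                                               model_config, seed, t_star)
    perm_stats, perm_aucs = [], []
    failed = 0
    n = len(cl)
    for b in range(B):
        rng = child_rng(seed, TAG_PERM_OUTCOME, b)
        perm = rng.permutation(n)
        cl_b = cl.copy()
        moved = ["dfs_time", "dfs_event", "os_time", "os_event"]
        if shuffle_stage_with_outcome:
            moved.append("stage")
        cl_b[moved] = cl[moved].to_numpy()[perm]
        try:
            stat_b, auc_b, _ = _pipeline_stats(
                expr, cl_b, endpoint, model_config,
                child_seed(seed, TAG_PERM_OUTCOME, b), t_star)
        except (DegenerateFitError, ValueError) as exc:
            warnings.warn(f"permutation {b} skipped: {exc}")
            failed += 1
            continue
        perm_stats.append(stat_b)
        perm_aucs.append(auc_b)
    return {
        "observed_logrank": obs_stat,
        "observed_auc": obs_auc,
        "cv_pi": cv_pi,
        "p_logrank": _perm_pvalue(obs_stat, perm_stats),
        "p_auc_vs_half": _perm_pvalue(abs(obs_auc - 0.5),
                                      [abs(a - 0.5) for a in perm_aucs]),
        "n_permutations": len(perm_stats),
        "n_failed": failed,
    }


def added_value_permutation_test(expr: ExpressionMatrix, clinical: pd.DataFrame,
                                 endpoint: str, B: int = 1000, seed: int = 0,
                                 model_config: ModelConfig | None = None,
                                 t_star: float = 24.0) -> dict:
    """miRNA-reassignment permutation test of added predictive value.

    The correspondence between time, event status and clinical covariates
    is kept intact; only the miRNA rows are shuffled against them, so the
    null is "survival and clinical covariates are independent of the
    miRNAs".  Observed statistics come from the combined model; the
    clinical-only model's statistics are reported alongside.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    model_config = model_config or ModelConfig()
    cl = clinical.reset_index(drop=True)
    time_col, event_col = endpoint_columns(endpoint)
    obs_stat, obs_auc, cv_pi = _pipeline_stats(expr, cl, endpoint,
                                               model_config, seed, t_star)
    clin_stat, clin_auc, _ = _pipeline_stats(None, cl, endpoint,
                                             model_config, seed, t_star)
    perm_stats, perm_aucs = [], []
    failed = 0
    n = len(cl)
    for b in range(B):
        rng = child_rng(seed, TAG_PERM_MIRNA, b)
        perm = rng.permutation(n)
        expr_b = ExpressionMatrix(patient_ids=list(expr.patient_ids),
                                  mirna_ids=list(expr.mirna_ids),
                                  value=expr.value[perm])
        try:
            stat_b, auc_b, _ = _pipeline_stats(
                expr_b, cl, endpoint, model_config,
                child_seed(seed, TAG_PERM_MIRNA, b), t_star)
        except (DegenerateFitError, ValueError) as exc:
            warnings.warn(f"permutation {b} skipped: {exc}")
            failed += 1
            continue
        perm_stats.append(stat_b)
        perm_aucs.append(auc_b)
    return {
        "observed_logrank": obs_stat,
        "observed_auc": obs_auc,
        "cv_pi": cv_pi,
        "clinical_only_logrank": clin_stat,
        "clinical_only_auc": clin_auc,
        "p_logrank": _perm_pvalue(obs_stat, perm_stats),
        "p_auc": _perm_pvalue(obs_auc, perm_aucs),
        "n_permutations": len(perm_stats),
        "n_failed": failed,
    }


def validate_model(expr: ExpressionMatrix, clinical: pd.DataFrame,
                   endpoint: str, model_config: ModelConfig | None = None,
                   B: int = 1000, t_star: float = 24.0, seed: int = 0,
                   ) -> ValidationReport:
    """Full validation: LOOCV, risk groups, K–M, ROC, all permutation tests."""
    model_config = model_config or ModelConfig()
    cl = clinical.reset_index(drop=True)
    time_col, event_col = endpoint_columns(endpoint)
    times = cl[time_col].to_numpy(dtype=float)
    events = cl[event_col].to_numpy(dtype=bool)

    outcome_perm = permutation_test_logrank(expr, cl, endpoint, B=B, seed=seed,
                                            model_config=model_config,
                                            t_star=t_star)
    cv_pi = outcome_perm["cv_pi"]
    group, km, stat = cv_km_and_logrank(cv_pi, cl, endpoint)
    roc = cv_time_dependent_roc(cv_pi, times, events, t_star)
    added = added_value_permutation_test(expr, cl, endpoint, B=B, seed=seed,
                                         model_config=model_config,
                                         t_star=t_star)
    return ValidationReport(
        endpoint=endpoint, cv_pi=cv_pi, risk_group=group, cv_km=km,
        cv_logrank_stat=stat, p_logrank_perm=outcome_perm["p_logrank"],
        roc_time=t_star, cv_roc=roc.curve, cv_auc=roc.auc,
        p_auc_vs_half=outcome_perm["p_auc_vs_half"],
        p_added_value_logrank=added["p_logrank"],
        p_added_value_auc=added["p_auc"],
        n_permutations=B,
        clinical_only_logrank_stat=added["clinical_only_logrank"],
        clinical_only_auc=added["clinical_only_auc"],
        n_failed_permutations=outcome_perm["n_failed"] + added["n_failed"])
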