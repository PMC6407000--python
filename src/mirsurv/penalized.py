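"""Elastic-net Cox with unpenalized clinical covariates and a selection cap.

The combined multivariable model regresses a right-censored endpoint on
all miRNAs (penalized) plus clinical covariates such as disease stage
(unpenalized, penalty factor 0), with the elastic-net mixing parameter
alpha = 0.5 by default.  The number of *penalized* variables allowed into
the model is capped (default 5) by truncating the regularization path at
the first lambda where the cap would be exceeded — the standard device in
penalized-path software, never post-hoc deletion.  The regularization
strength is then chosen by K-fold cross-validated partial-likelihood
deviance (Verweij–van Houwelingen), with folds stratified by event status
and reproducible from a seed.

miRNA columns are standardized internally (mean 0, SD 1) before
penalization so the cap is meaningful across scales; coefficients are
reported back on the −ΔCT scale.  Clinical columns are left untouched.

Coordinate-descent path fitting is delegated to scikit-survival's Coxnet;
the path truncation, CV deviance and lambda selection are implemented
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._seeds import TAG_CVFOLDS, child_rng
from .datatypes import ExpressionMatrix, coarse_stage, endpoint_columns


class DegenerateFitError(RuntimeError):
    """A fit whose prognostic index cannot rank patients."""


def cox_breslow_loglik(eta: np.ndarray, times: np.ndarray,
                       events: np.ndarray) -> float:
    """Cox partial log-likelihood at a fixed linear predictor (Breslow ties)."""
    eta = np.asarray(eta, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    order = np.argsort(times, kind="stable")
    eta_o, t_o, e_o = eta[order], times[order], events[order]
    m = eta_o.max()
    # risk-set denominator: sum of exp(eta) over all with time >= t, where
    # tied subjects share the denominator of their tie block's first index
    rev_cum = np.cumsum(np.exp(eta_o - m)[::-1])[::-1]
    block_start = np.searchsorted(t_o, t_o, side="left")
    log_denom = m + np.log(rev_cum[block_start])
    return float((eta_o[e_o] - log_denom[e_o]).sum())


@dataclass
class ModelConfig:
    """Tunable knobs of the combined model (shared by the validation engine)."""

    alpha: float = 0.5                 # elastic-net mixing (1 = lasso)
    max_selected: int | None = 5       # cap on penalized (miRNA) variables
    folds: int = 10                    # inner CV folds for lambda
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    clinical_covariates: tuple[str, ...] = ("stage",)


@dataclass
class PenalizedCoxFit:
    """A fitted combined model at the CV-selected regularization strength."""

    terms: list[str]                   # clinical dummies first, then miRNAs
    clinical_terms: list[str]
    mirna_ids: list[str]
    beta: np.ndarray                   # on the original (−ΔCT) scale
    penalty_factor: np.ndarray
    alpha: float
    lambda_path: np.ndarray            # admissible (truncated) path
    lambda_selected: float
    lambda_index: int
    cv_deviance_mean: np.ndarray
    cv_deviance_se: np.ndarray
    selected_mirnas: list[str]
    max_selected: int | None
    dropped_constant: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "clinical_terms": self.clinical_terms,
            "beta": self.beta.tolist(),
            "penalty_factor": self.penalty_factor.tolist(),
            "alpha": self.alpha,
            "lambda_path": self.lambda_path.tolist(),
            "lambda_selected": self.lambda_selected,
            "lambda_index": self.lambda_index,
            "cv_deviance_mean": self.cv_deviance_mean.tolist(),
            "cv_deviance_se": self.cv_deviance_se.tolist(),
            "selected_mirnas": self.selected_mirnas,
            "max_selected": self.max_selected,
            "dropped_constant": self.dropped_constant,
        }

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "beta": self.beta,
            "penalized": self.penalty_factor.astype(bool),
        })


def build_design(expr: ExpressionMatrix | None, clinical: pd.DataFrame,
                 clinical_covariates: tuple[str, ...] = ("stage",),
                 ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Design matrix [clinical dummies | miRNAs] with 0/1 penalty factors.

    Clinical covariates expand to dummies against their reference level
    (stage I, female, never-smoker, no treatment); ``expr`` may be None for
    a clinical-only design.
    """
    cols: dict[str, np.ndarray] = {}
    for name in clinical_covariates:
        series = clinical[name] if name != "stage" else coarse_stage(clinical["stage"])
        if series.dtype == object or series.dtype == bool or isinstance(
                series.dtype, pd.CategoricalDtype):
            from .screen import REFERENCE_LEVELS
            levels = sorted(pd.unique(series.dropna()), key=str)
            ref = REFERENCE_LEVELS.get(name)
            if ref not in levels:
                ref = levels[0]
            for lv in levels:
                if lv == ref:
                    continue
                cols[f"{name}={lv}"] = (series == lv).to_numpy(dtype=float)
        else:
            cols[name] = series.to_numpy(dtype=float)
    clinical_terms = list(cols)
    if expr is not None:
        if np.isnan(expr.value).any():
            raise ValueError("expression matrix contains missing values; impute first")
        for gi, gid in enumerate(expr.mirna_ids):
            cols[gid] = expr.value[:, gi]
    X = pd.DataFrame(cols)
    pf = np.array([0.0] * len(clinical_terms) +
                  [1.0] * (X.shape[1] - len(clinical_terms)))
    return X, pf, clinical_terms


def _stratified_folds(events: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold labels 0..K-1, stratified by event status."""
    assign = np.empty(len(events), dtype=int)
    for flag in (True, False):
        idx = np.flatnonzero(events == flag)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % n_folds
    return assign


def _coxnet_path(X: np.ndarray, y, alpha: float, pf: np.ndarray,
                 alphas: np.ndarray | None, n_alphas: int,
                 min_ratio: float) -> tuple[np.ndarray, np.ndarray]:
    """Fit a Coxnet path; returns (lambdas, coef matrix p × n_lambdas)."""
    kw: dict = dict(l1_ratio=alpha, penalty_factor=pf, normalize=False,
                    tol=1e-9, max_iter=200000)
    if alphas is not None:
        model = CoxnetSurvivalAnalysis(alphas=list(alphas), **kw)
    else:
        model = CoxnetSurvivalAnalysis(n_alphas=n_alphas,
                                       alpha_min_ratio=min_ratio, **kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return np.asarray(model.alphas_), np.asarray(model.coef_)


def _truncated_path(X: np.ndarray, y, alpha: float, pf: np.ndarray,
                    config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Geometric lambda path truncated before the cap is first exceeded.

    The grid is the standard ``n_lambda`` geometric sequence from the
    data-derived lambda_max down to ``lambda_min_ratio``·lambda_max; only
    the head up to (excluding) the first lambda whose fit would carry more
    than ``max_selected`` nonzero penalized coefficients is kept.  Fitting
    proceeds in grid-aligned chunks so the usual case touches only the
    sparse head of the path.
    """
    n_total = config.n_lambda
    penalized = pf > 0
    cap = config.max_selected
    for k in (16, 32, 64, n_total):
        k = min(k, n_total)
        ratio = config.lambda_min_ratio ** ((k - 1) / (n_total - 1))
        lambdas, coefs = _coxnet_path(X, y, alpha, pf, None, k, ratio)
        nnz = (np.abs(coefs[penalized, :]) > 0).sum(axis=0)
        if cap is not None:
            over = np.flatnonzero(nnz > cap)
            if over.size:
                cut = over[0]
                if cut < 1:
                    cut = 1   # lambda_max itself is always admissible
                return lambdas[:cut], coefs[:, :cut]
        if k == n_total:
            return lambdas, coefs
    raise AssertionError("unreachable")


def fit_elastic_net_cox(expr: ExpressionMatrix, clinical: pd.DataFrame,
                        endpoint: str, config: ModelConfig | None = None,
                        seed: int = 0) -> PenalizedCoxFit:
    """Fit the combined model and choose lambda by K-fold CV deviance.

    The CV criterion is the Verweij–van Houwelingen partial-likelihood
    deviance: for fold k, ``-2·[pl(beta_-k; all) − pl(beta_-k; train)]``.
    The admissible lambda minimizing the mean deviance is selected, ties
    going to the larger (more parsimonious) lambda.
    """
    config = config or ModelConfig()
    time_col, event_col = endpoint_columns(endpoint)
    cl = clinical.set_index("patient_id").loc[expr.patient_ids].reset_index()
    times = cl[time_col].to_numpy(dtype=float)
    events = cl[event_col].to_numpy(dtype=bool)
    if events.sum() < config.folds:
        raise ValueError(
            f"{int(events.sum())} events < {config.folds} folds; use fewer folds")

    X_df, pf, clinical_terms = build_design(expr, cl, config.clinical_covariates)
    # drop all-constant miRNA columns (cannot be scaled or selected)
    Xarr = X_df.to_numpy(dtype=float)
    col_sd = Xarr.std(axis=0, ddof=0)
    col_scale = np.maximum(1.0, np.abs(Xarr).max(axis=0))
    dropped = [c for c, p_, sd, sc in zip(X_df.columns, pf, col_sd, col_scale)
               if p_ > 0 and sd <= 1e-12 * sc]
    if dropped:
        warnings.warn(f"dropping constant miRNA columns: {dropped}")
        keep = [c for c in X_df.columns if c not in dropped]
        X_df = X_df[keep]
        pf = np.array([0.0 if c in clinical_terms else 1.0 for c in keep])
    terms = list(X_df.columns)
    mirna_ids = [t for t in terms if t not in clinical_terms]

    X = X_df.to_numpy(dtype=float)
    penalized = pf > 0
    center = np.where(penalized, X.mean(axis=0), 0.0)
    scale = np.where(penalized, X.std(axis=0, ddof=0), 1.0)
    Xs = (X - center) / scale
    y = Surv.from_arrays(events, times)

    lambdas, coefs = _truncated_path(Xs, y, config.alpha, pf, config)

    rng = child_rng(seed, TAG_CVFOLDS)
    folds = _stratified_folds(events, config.folds, rng)
    dev = np.full((config.folds, len(lambdas)), np.nan)
    for k in range(config.folds):
        tr = folds != k
        try:
            _, coefs_k = _coxnet_path(Xs[tr], y[tr], config.alpha, pf,
                                      lambdas, 0, 0.0)
        except (ValueError, ArithmeticError):
            continue
        for li in range(coefs_k.shape[1]):
            eta_all = Xs @ coefs_k[:, li]
            ll_all = cox_breslow_loglik(eta_all, times, events)
            ll_tr = cox_breslow_loglik(eta_all[tr], times[tr], events[tr])
            dev[k, li] = -2.0 * (ll_all - ll_tr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dev_mean = np.nanmean(dev, axis=0)
        dev_se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(
            np.sum(~np.isnan(dev), axis=0).clip(min=1))
    if np.all(np.isnan(dev_mean)):
        raise DegenerateFitError("all CV folds failed")
    best = int(np.nanargmin(dev_mean))   # first minimum = largest lambda on ties

    beta_std = coefs[:, best]
    beta = beta_std / scale
    selected = [t for t, b, is_pen in zip(terms, beta, penalized)
                if is_pen and b != 0.0]
    return PenalizedCoxFit(
        terms=terms, clinical_terms=clinical_terms, mirna_ids=mirna_ids,
        beta=beta, penalty_factor=pf, alpha=config.alpha,
        lambda_path=lambdas, lambda_selected=float(lambdas[best]),
        lambda_index=best, cv_deviance_mean=dev_mean, cv_deviance_se=dev_se,
        selected_mirnas=selected, max_selected=config.max_selected,
        dropped_constant=dropped)


def prognostic_index(fit: PenalizedCoxFit, expr: ExpressionMatrix | None,
                     clinical: pd.DataFrame) -> np.ndarray:
    """Linear predictor x'beta for each patient (no baseline hazard needed).

    The design is reconstructed from the fitted terms, so dummy columns for
    levels absent from ``clinical`` (e.g. when scoring a single held-out
    patient) are simply zero rather than missing.
    """
    cl = clinical.reset_index(drop=True)
    mirna_index = ({g: i for i, g in enumerate(expr.mirna_ids)}
                   if expr is not None else {})
    cols = []
    for t in fit.terms:
        if t in fit.clinical_terms:
            if "=" in t:
                name, lv = t.split("=", 1)
                series = (coarse_stage(cl["stage"]) if name == "stage"
                          else cl[name])
                cols.append((series.astype(str) == lv).to_numpy(dtype=float))
            else:
                cols.append(cl[t].to_numpy(dtype=float))
        else:
            if t not in mirna_index:
                raise ValueError(f"design is missing fitted term {t!r}")
            cols.append(expr.value[:, mirna_index[t]])
    X = np.column_stack(cols)
    return X @ fit.beta


def fit_clinical_cox(clinical: pd.DataFrame, endpoint: str,
                     clinical_covariates: tuple[str, ...] = ("stage",),
                     ) -> PenalizedCoxFit:
    """Unpenalized Cox on the clinical covariates only (lifelines, Efron).

    Returned in :class:`PenalizedCoxFit` form (empty miRNA block) so the
    validation engine can treat the stage-only model uniformly.
    """
    time_col, event_col = endpoint_columns(endpoint)
    cl = clinical.reset_index(drop=True)
    X_df, pf, clinical_terms = build_design(None, cl, clinical_covariates)
    df = X_df.copy()
    df["_time"] = cl[time_col].to_numpy(dtype=float)
    df["_event"] = cl[event_col].to_numpy(dtype=int)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_time", event_col="_event")
    beta = np.array([float(cph.params_[t]) for t in X_df.columns])
    return PenalizedCoxFit(
        terms=list(X_df.columns), clinical_terms=clinical_terms, mirna_ids=[],
        beta=beta, penalty_factor=pf, alpha=0.0,
        lambda_path=np.array([0.0]), lambda_selected=0.0, lambda_index=0,
        cv_deviance_mean=np.array([np.nan]), cv_deviance_se=np.array([np.nan]),
        selected_mirnas=[], max_selected=None)
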