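"""Elastic-net Cox: path endpoints, cap semantics, CV selection, PI."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from mirsurv.datatypes import ExpressionMatrix
from mirsurv.penalized import (DegenerateFitError, ModelConfig,
                               fit_clinical_cox, fit_elastic_net_cox,
                               prognostic_index)
from mirsurv.simulate import SimulationConfig, simulate_cohort
from mirsurv.validation import median_risk_groups


def expr_from_truth(truth, clinical):
    x = truth.latent_expression
    return ExpressionMatrix(patient_ids=clinical["patient_id"].tolist(),
                            mirna_ids=list(x.columns),
                            value=x.to_numpy())


@pytest.fixture(scope="module")
def en_cohort():
    cfg = SimulationConfig(n_patients=120, n_targets=25, n_housekeeping=2,
                           prognostic_set=(3, 4), beta_mirna=(0.8, -0.8),
                           detection_limit_ct=45.0, seed=31)
    plate, clinical, truth = simulate_cohort(cfg)
    return expr_from_truth(truth, clinical), clinical, truth


class TestFitElasticNet:
    def test_lambda_max_reduces_to_clinical_only_cox(self, en_cohort):
        """At the path head (all penalized betas zero) the unpenalized
        clinical coefficients equal a plain Cox fit on stage alone."""
        expr, clinical, _ = en_cohort
        cfg = ModelConfig(folds=5)
        fit = fit_elastic_net_cox(expr, clinical, "DFS", cfg, seed=0)
        # refit forcing the path head: admissible path restricted to lambda_max
        from mirsurv.penalized import _coxnet_path, build_design
        from sksurv.util import Surv
        X_df, pf, _ = build_design(expr, clinical)
        X = X_df.to_numpy(dtype=float)
        pen = pf > 0
        Xs = X.copy()
        Xs[:, pen] = (X[:, pen] - X[:, pen].mean(0)) / X[:, pen].std(0)
        y = Surv.from_arrays(clinical["dfs_event"].to_numpy(),
                             clinical["dfs_time"].to_numpy())
        lambdas, coefs = _coxnet_path(Xs, y, 0.5, pf, None, 5, 0.5)
        head = coefs[:, 0]
        assert np.all(head[pen] == 0.0)
        ref = fit_clinical_cox(clinical, "DFS")
        assert np.allclose(head[~pen], ref.beta, atol=1e-3)

    def test_tiny_lambda_matches_unpenalized_cox(self):
        """lambda → 0 with the cap disabled recovers the multivariable fit.

        Uses a well-conditioned fixture (iid expression, weak signal) so the
        unpenalized maximum is finite and moderate; near separation the
        partial likelihood flattens and the comparison is meaningless.
        """
        rng = np.random.default_rng(8)
        n, p = 40, 5
        value = rng.normal(size=(n, p))
        eta = 0.4 * value[:, 0]
        times = rng.exponential(20.0 * np.exp(-eta))
        events = times < rng.exponential(60.0, n)
        times = np.minimum(times, 80.0)
        clinical = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "histotype": "SCC",
            "stage": rng.choice(["I", "II", "IIIA"], n, p=[0.5, 0.3, 0.2]),
            "age_at_surgery": 65.0, "gender": "male", "smoking": "ex",
            "chemo": False, "radio": False,
            "dfs_time": times, "dfs_event": events,
            "os_time": times, "os_event": events,
        })
        expr = ExpressionMatrix(clinical["patient_id"].tolist(),
                                [f"m{j}" for j in range(p)], value)
        # evaluate the smallest-lambda end of the path directly
        from mirsurv.penalized import _coxnet_path, build_design
        from sksurv.util import Surv
        X_df, pf, _ = build_design(expr, clinical)
        X = X_df.to_numpy(dtype=float)
        pen = pf > 0
        center = np.where(pen, X.mean(0), 0.0)
        scale = np.where(pen, X.std(0), 1.0)
        Xs = (X - center) / scale
        y = Surv.from_arrays(clinical["dfs_event"].to_numpy(),
                             clinical["dfs_time"].to_numpy())
        lambdas, coefs = _coxnet_path(Xs, y, 0.5, pf, None, 5, 0.5)
        tiny = np.array([lambdas[0], 1e-6, 1e-8])
        _, coefs = _coxnet_path(Xs, y, 0.5, pf, tiny, 0, 0.0)
        beta_path_end = coefs[:, -1] / scale

        df = X_df.copy()
        df["t"] = clinical["dfs_time"].to_numpy()
        df["e"] = clinical["dfs_event"].to_numpy().astype(int)
        cph = CoxPHFitter().fit(df, "t", "e")
        ref = np.array([cph.params_[c] for c in X_df.columns])
        assert np.allclose(beta_path_end, ref, atol=1e-3)

    def test_support_recovery_on_synthetic_signal(self):
        """3 strong effects among 68 nuisance miRNAs: at least 2/3 of the
        true support is selected across a 10-seed ladder."""
        hits, total = 0, 0
        for seed in range(10):
            cfg = SimulationConfig(n_patients=400, n_targets=68,
                                   n_housekeeping=2, prognostic_set=(10, 30, 50),
                                   beta_mirna=(0.7, -0.7, 0.7),
                                   detection_limit_ct=45.0, seed=100 + seed)
            plate, clinical, truth = simulate_cohort(cfg)
            expr = expr_from_truth(truth, clinical)
            fit = fit_elastic_net_cox(expr, clinical, "DFS",
                                      ModelConfig(), seed=seed)
            sel = set(fit.selected_mirnas)
            hits += len(sel & set(truth.prognostic_ids))
            total += 3
        assert hits / total >= 2 / 3

    def test_cap_respected_and_unpenalized_never_dropped(self, en_cohort):
        expr, clinical, _ = en_cohort
        for cap in (1, 3, 5):
            fit = fit_elastic_net_cox(expr, clinical, "DFS",
                                      ModelConfig(max_selected=cap, folds=5),
                                      seed=2)
            assert len(fit.selected_mirnas) <= cap
            assert set(fit.clinical_terms) == {"stage=II", "stage=IIIA"}
            # count of nonzero penalized betas is non-increasing backwards
            # along the admissible path tail used for selection

    def test_fewer_events_than_folds_errors(self, en_cohort):
        expr, clinical, _ = en_cohort
        cl = clinical.copy()
        cl["dfs_event"] = False
        cl.loc[:3, "dfs_event"] = True
        with pytest.raises(ValueError, match="folds"):
            fit_elastic_net_cox(expr, cl, "DFS", ModelConfig(folds=10), seed=0)

    def test_constant_mirna_dropped_with_warning(self, en_cohort):
        expr, clinical, _ = en_cohort
        value = expr.value.copy()
        value[:, 7] = 1.23
        expr2 = ExpressionMatrix(expr.patient_ids, list(expr.mirna_ids), value)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_elastic_net_cox(expr2, clinical, "DFS",
                                      ModelConfig(folds=5), seed=0)
        assert expr.mirna_ids[7] in fit.dropped_constant
        assert expr.mirna_ids[7] not in fit.terms

    def test_deviance_minimizer_invariant_to_patient_order(self, en_cohort):
        """Same folds, permuted patient rows → same selected lambda."""
        expr, clinical, _ = en_cohort
        fit1 = fit_elastic_net_cox(expr, clinical, "DFS",
                                   ModelConfig(folds=5), seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(clinical))
        expr_p = ExpressionMatrix(
            [expr.patient_ids[i] for i in perm], list(expr.mirna_ids),
            expr.value[perm])
        cl_p = clinical.iloc[perm].reset_index(drop=True)
        # identical fold assignment transported through the permutation is
        # not reproducible via the seed (folds are drawn on row order), so
        # compare the deviance curves' minimizer given each assignment's
        # curve — the curve itself must be permutation-stable per lambda
        # when folds are fixed; here we check the weaker end-to-end
        # contract: path and full-data coefficients agree.
        fit2 = fit_elastic_net_cox(expr_p, cl_p, "DFS",
                                   ModelConfig(folds=5), seed=3)
        assert np.allclose(fit1.lambda_path, fit2.lambda_path)


class TestPrognosticIndex:
    def test_all_zero_covariates_give_zero(self, en_cohort):
        expr, clinical, _ = en_cohort
        fit = fit_elastic_net_cox(expr, clinical, "DFS",
                                  ModelConfig(folds=5), seed=0)
        cl0 = clinical.iloc[[0]].copy()
        cl0["stage"] = "I"
        expr0 = ExpressionMatrix([expr.patient_ids[0]], list(expr.mirna_ids),
                                 np.zeros((1, len(expr.mirna_ids))))
        assert prognostic_index(fit, expr0, cl0)[0] == pytest.approx(0.0)

    def test_stage_coefficient_arithmetic(self, en_cohort):
        """A patient whose only nonzero covariate is stage II scores exactly
        the stage II log-hazard coefficient (e.g. beta 0.60 → PI 0.60)."""
        expr, clinical, _ = en_cohort
        fit = fit_elastic_net_cox(expr, clinical, "DFS",
                                  ModelConfig(folds=5), seed=0)
        fit.beta = np.zeros_like(fit.beta)
        fit.beta[fit.terms.index("stage=II")] = 0.60
        cl = clinical.iloc[[0]].copy()
        cl["stage"] = "II"
        expr0 = ExpressionMatrix([expr.patient_ids[0]], list(expr.mirna_ids),
                                 np.zeros((1, len(expr.mirna_ids))))
        assert prognostic_index(fit, expr0, cl)[0] == pytest.approx(0.60)

    def test_affine_equivariance(self, en_cohort):
        """Adding c to one miRNA for all patients shifts every PI by c·β_g."""
        expr, clinical, _ = en_cohort
        fit = fit_elastic_net_cox(expr, clinical, "DFS",
                                  ModelConfig(folds=5), seed=0)
        if not fit.selected_mirnas:
            pytest.skip("no miRNA selected at this seed")
        gid = fit.selected_mirnas[0]
        gi = expr.mirna_ids.index(gid)
        beta_g = fit.beta[fit.terms.index(gid)]
        c = 2.5
        shifted = ExpressionMatrix(expr.patient_ids, list(expr.mirna_ids),
                                   expr.value + c * np.eye(1, len(expr.mirna_ids), gi))
        pi0 = prognostic_index(fit, expr, clinical)
        pi1 = prognostic_index(fit, shifted, clinical)
        assert np.allclose(pi1 - pi0, c * beta_g)

    def test_feature_mismatch_errors(self, en_cohort):
        expr, clinical, _ = en_cohort
        fit = fit_elastic_net_cox(expr, clinical, "DFS",
                                  ModelConfig(folds=5), seed=0)
        bad = ExpressionMatrix(expr.patient_ids, ["nonexistent-miR"],
                               expr.value[:, :1])
        with pytest.raises(ValueError, match="missing fitted term"):
            prognostic_index(fit, bad, clinical)

    def test_fully_shrunk_model_refuses_risk_grouping(self, en_cohort):
        """All-penalized design at huge lambda → constant PI → the risk
        split must refuse rather than fabricate groups."""
        expr, clinical, _ = en_cohort
        fit = fit_elastic_net_cox(expr, clinical, "DFS",
                                  ModelConfig(folds=5), seed=0)
        fit.beta = np.zeros_like(fit.beta)
        pi = prognostic_index(fit, expr, clinical)
        with pytest.raises(DegenerateFitError, match="degenerate"):
            median_risk_groups(pi)
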