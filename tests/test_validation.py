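"""LOOCV scoring, risk splits, time-dependent ROC and permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from mirsurv._seeds import TAG_LOOCV, child_seed
from mirsurv.datatypes import ExpressionMatrix
from mirsurv.penalized import (DegenerateFitError, ModelConfig,
                               fit_elastic_net_cox, prognostic_index)
from mirsurv.simulate import SimulationConfig, simulate_cohort
from mirsurv.validation import (added_value_permutation_test,
                                cv_km_and_logrank, cv_time_dependent_roc,
                                loocv_prognostic_indices, median_risk_groups,
                                permutation_test_logrank)

FAST = ModelConfig(folds=4, n_lambda=50)


def small_cohort(n=25, n_targets=10, beta=(0.9,), prog=(2,), seed=41,
                 beta_stage=(0.6, 1.2)):
    cfg = SimulationConfig(n_patients=n, n_targets=n_targets,
                           n_housekeeping=2, prognostic_set=prog,
                           beta_mirna=beta, beta_stage=beta_stage,
                           detection_limit_ct=45.0, seed=seed)
    _, clinical, truth = simulate_cohort(cfg)
    expr = ExpressionMatrix(clinical["patient_id"].tolist(),
                            list(truth.latent_expression.columns),
                            truth.latent_expression.to_numpy())
    return expr, clinical


class TestLoocv:
    def test_matches_independent_reference_loop(self):
        """The engine's LOOCV equals a plain explicit loop, bit for bit."""
        expr, clinical = small_cohort(n=25)
        seed = 3
        got = loocv_prognostic_indices(expr, clinical, "DFS", FAST, seed=seed)

        ref = np.empty(len(clinical))
        for i in range(len(clinical)):
            keep = [j for j in range(len(clinical)) if j != i]
            expr_tr = ExpressionMatrix(
                [expr.patient_ids[j] for j in keep], list(expr.mirna_ids),
                expr.value[keep])
            cl_tr = clinical.iloc[keep].reset_index(drop=True)
            fit = fit_elastic_net_cox(expr_tr, cl_tr, "DFS", FAST,
                                      seed=child_seed(seed, TAG_LOOCV, i))
            beta = dict(zip(fit.terms, fit.beta))
            stage = clinical.iloc[i]["stage"]
            pi = (beta.get("stage=II", 0.0) * (stage == "II")
                  + beta.get("stage=IIIA", 0.0) * (stage == "IIIA"))
            for g, gid in enumerate(expr.mirna_ids):
                pi += beta.get(gid, 0.0) * expr.value[i, g]
            ref[i] = pi
        np.testing.assert_array_equal(got, ref)

    def test_duplicated_cohort_near_equivalence(self):
        """Leaving one copy of a duplicated patient out scores it close to
        the full-data prognostic index."""
        expr, clinical = small_cohort(n=20, seed=43)
        expr2 = ExpressionMatrix(
            expr.patient_ids + [p + "b" for p in expr.patient_ids],
            list(expr.mirna_ids), np.vstack([expr.value, expr.value]))
        cl2 = pd.concat([clinical, clinical.assign(
            patient_id=clinical["patient_id"] + "b")], ignore_index=True)
        fit = fit_elastic_net_cox(expr2, cl2, "DFS", FAST, seed=1)
        full_pi = prognostic_index(fit, expr2, cl2)
        cv_pi = loocv_prognostic_indices(expr2, cl2, "DFS", FAST, seed=1)
        # compare on rank correlation: exact betas differ fold by fold
        rho = np.corrcoef(rankdata(full_pi), rankdata(cv_pi))[0, 1]
        assert rho > 0.7

    def test_reproducible_from_seed(self):
        expr, clinical = small_cohort(n=22, seed=47)
        a = loocv_prognostic_indices(expr, clinical, "DFS", FAST, seed=9)
        b = loocv_prognostic_indices(expr, clinical, "DFS", FAST, seed=9)
        np.testing.assert_array_equal(a, b)


class TestRiskSplit:
    def test_median_split_counts_balanced(self):
        group = median_risk_groups(np.arange(10.0))
        assert (group == "high").sum() == 5

    def test_odd_n_low_gets_extra(self):
        group = median_risk_groups(np.arange(11.0))
        assert (group == "low").sum() == 6
        assert (group == "high").sum() == 5

    def test_exact_median_ties_go_low(self):
        group = median_risk_groups(np.array([1.0, 2.0, 2.0, 3.0]))
        assert list(group) == ["low", "low", "low", "high"]

    def test_constant_pi_refused(self):
        with pytest.raises(DegenerateFitError):
            median_risk_groups(np.full(10, 1.5))

    def test_logrank_on_perfectly_ordered_small_cohort(self):
        """cv_pi ordered with event times, no censoring: the log-rank
        chi-square matches a direct hand computation on n=8."""
        times = np.arange(1.0, 9.0)
        events = np.ones(8, dtype=bool)
        cv_pi = -times  # highest risk dies first
        clinical = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(8)],
            "dfs_time": times, "dfs_event": events,
            "os_time": times, "os_event": events,
        })
        _, km, stat = cv_km_and_logrank(cv_pi, clinical, "DFS")
        # hand computation: high group = 4 earliest deaths (pi > median)
        # O-E over event times for group "high": at t=1..4 high members die
        # while at risk sets shrink; E = sum d_t * n_high_t / n_t
        n_high, n_low = 4, 4
        e_high, var = 0.0, 0.0
        nh, nl = n_high, n_low
        o_high = 4
        for t in range(1, 9):
            n_t = nh + nl
            e_high += nh / n_t
            var += (nh * nl) / (n_t ** 2)
            if t <= 4:
                nh -= 1
            else:
                nl -= 1
        expected_stat = (o_high - e_high) ** 2 / var
        assert stat == pytest.approx(expected_stat, rel=1e-9)


class TestTimeDependentRoc:
    def test_no_censoring_equals_rank_sum(self):
        """Without censoring the IPCW AUC is the plain Mann–Whitney AUC of
        cases (event by t) vs controls (event-free at t)."""
        rng = np.random.default_rng(2)
        n = 40
        times = rng.uniform(1, 100, n)
        events = np.ones(n, dtype=bool)
        pi = 0.03 * (100 - times) + rng.normal(0, 0.3, n)
        t_star = 50.0
        roc = cv_time_dependent_roc(pi, times, events, t_star)
        case = times <= t_star
        ranks = rankdata(pi)
        n1, n0 = case.sum(), (~case).sum()
        auc_rank = (ranks[case].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert roc.auc == pytest.approx(auc_rank, abs=1e-12)

    def test_constant_pi_gives_half(self):
        times = np.arange(1.0, 21.0)
        events = np.ones(20, dtype=bool)
        roc = cv_time_dependent_roc(np.full(20, 2.0), times, events, 10.0)
        assert roc.auc == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        times = np.arange(1.0, 21.0)
        events = np.ones(20, dtype=bool)
        pi = -times
        roc = cv_time_dependent_roc(pi, times, events, 10.0)
        assert roc.auc == pytest.approx(1.0)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(7)
        n = 60
        times = rng.exponential(40, n)
        events = rng.random(n) < 0.7
        times = np.minimum(times, 90.0)
        pi = rng.normal(size=n)
        a1 = cv_time_dependent_roc(pi, times, events, 30.0).auc
        a2 = cv_time_dependent_roc(-pi, times, events, 30.0).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_sksurv_uno_estimator_under_censoring(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv
        rng = np.random.default_rng(11)
        n = 80
        times = rng.exponential(40, n)
        cens = rng.exponential(70, n)
        obs = np.minimum(times, cens)
        events = times <= cens
        pi = -np.log(times) + rng.normal(0, 0.8, n)
        roc = cv_time_dependent_roc(pi, obs, events, 30.0)
        y = Surv.from_arrays(events, obs)
        ref, _ = cumulative_dynamic_auc(y, y, pi, [30.0])
        assert roc.auc == pytest.approx(float(ref[0]), abs=1e-6)

    def test_errors_without_events_or_at_risk(self):
        times = np.array([50.0, 60.0, 70.0])
        events = np.array([True, True, True])
        with pytest.raises(ValueError, match="no events"):
            cv_time_dependent_roc(np.arange(3.0), times, events, 10.0)
        with pytest.raises(ValueError, match="at risk"):
            cv_time_dependent_roc(np.arange(3.0), times, events, 80.0)

    def test_curve_is_monotone_staircase(self):
        rng = np.random.default_rng(3)
        n = 50
        times = rng.exponential(30, n)
        events = rng.random(n) < 0.8
        pi = rng.normal(size=n)
        roc = cv_time_dependent_roc(pi, np.minimum(times, 60), events, 20.0)
        assert (np.diff(roc.curve["fpr"]) >= -1e-12).all()
        assert (np.diff(roc.curve["tpr"]) >= -1e-12).all()
        assert roc.curve.iloc[0]["fpr"] == 0.0
        assert roc.curve.iloc[-1]["tpr"] == 1.0


class TestPermutationTests:
    def test_p_bounds_and_plus_one_convention(self):
        """Observed above every permuted value → p = 1/(B+1)."""
        expr, clinical = small_cohort(n=24, beta=(1.6,), seed=53)
        res = permutation_test_logrank(expr, clinical, "DFS", B=4, seed=5,
                                       model_config=FAST, t_star=24.0)
        assert 1 / 5 <= res["p_logrank"] <= 1.0
        assert res["n_permutations"] + res["n_failed"] == 4

    def test_added_value_reports_clinical_only_model(self):
        expr, clinical = small_cohort(n=24, seed=59)
        res = added_value_permutation_test(expr, clinical, "DFS", B=2,
                                           seed=7, model_config=FAST,
                                           t_star=24.0)
        assert np.isfinite(res["clinical_only_logrank"])
        assert 0.0 <= res["clinical_only_auc"] <= 1.0
        for key in ("p_logrank", "p_auc"):
            assert 1 / 3 <= res[key] <= 1.0

    def test_b_one_permuted_at_least_observed_gives_one(self):
        """With B=1, if the permuted statistic ties or beats the observed
        one the p-value is exactly 1."""
        rng = np.random.default_rng(0)
        from mirsurv.validation import _perm_pvalue
        assert _perm_pvalue(2.0, [2.0]) == 1.0
        assert _perm_pvalue(2.0, [1.0]) == 0.5

    def test_identical_outcomes_error_path(self):
        """All patients share one outcome → the log-rank split is undefined
        and the engine raises rather than fabricating a statistic."""
        expr, clinical = small_cohort(n=20, seed=61)
        cl = clinical.copy()
        cl["dfs_time"] = 10.0
        cl["dfs_event"] = False
        with pytest.raises((DegenerateFitError, ValueError)):
            permutation_test_logrank(expr, cl, "DFS", B=1, seed=0,
                                     model_config=FAST, t_star=5.0)
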