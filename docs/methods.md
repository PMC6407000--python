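# Methods

`mirsurv` implements a prognostic analysis of circulating miRNAs measured
by qPCR array in surgically resected early-stage non-small cell lung
cancer (NSCLC), with disease-free survival (DFS) and overall survival (OS)
as right-censored endpoints. Every stage is run separately per histotype
(squamous cell carcinoma, SCC; adenocarcinoma, ADC) and per endpoint —
never pooled. Because no patient-level cohort is distributed with the
package, a synthetic-data generator provides cohorts with the statistical
structure the analysis assumes; all tests and the acceptance script run on
generated data.

## qPCR normalization

Raw measurements are cycle-threshold (Ct) values: the PCR cycle at which a
well's fluorescence crosses threshold, lower meaning more template. Wells
that never cross threshold are "undetermined" and treated as missing.

1. **Spike-in centring.** An exogenous *C. elegans* miRNA (cel-miR-39) is
   added at RNA extraction as a technical recovery control. For patient
   *j*, the offset `spikein_ct_j − mean(spikein_ct)` is subtracted from
   every well. The spike-in itself is re-centred too, so the operation is
   idempotent (a deliberate choice; it simplifies pipeline restarts and
   costs nothing).
2. **Reference selection.** Two endogenous reference miRNAs are chosen by
   a model-based stability score: fit the additive two-way model
   `ct_gj = gene_g + sample_j + residual_gj` by row/column means over all
   complete (never-undetermined) candidate miRNAs, and score each gene by
   the standard deviation over patients of its residuals, with a
   small-sample factor G/(G−1) applied to the variance (G = number of
   candidate genes). Lower is more stable; ties break lexicographically
   by gene id. A grouped variant (inter-group gene-effect variance plus
   mean intra-group residual variance) is available via `groups` but is
   not the default, since the analysis defines no grouping. Ranking runs
   on spike-in-centred Ct of all complete retained miRNAs.
3. **−ΔCT.** The per-patient mean Ct of the two references is subtracted
   from every target; expression is reported as −ΔCT (a relative
   log2-scale abundance, higher = more expressed). The two references and
   the six housekeeping snRNA wells are excluded from all downstream
   statistics.

Two exact invariances follow and are tested to 1e-9: adding a constant to
every well of one patient (including spike-in and references) leaves −ΔCT
unchanged, as does adding a constant to every well of every patient.

## Missing data

Targets undetermined in **strictly more than 50%** of patients are
excluded. For the rest, a per-gene 2×2 table of undetermined-status ×
event-status is tested — Fisher's exact test when any expected cell count
is ≤ 5, otherwise Pearson's chi-square without continuity correction
(two-sided); degenerate margins are reported as not applicable. Remaining
undetermined wells are imputed by k-nearest neighbours: the distance
between two patients is the root-mean-square Ct difference over genes
observed in both; the k (default 5) nearest patients with the gene
observed contribute an unweighted mean. Imputation operates on
spike-in-centred Ct, before reference subtraction and within histotype,
so reference selection only ever sees complete data. All fills derive
from the original observed values, making the operation idempotent, and
each fill lies inside the observed range of its gene.

The neighbour count, distance and imputation scale are design choices
(the simplest defensible ones), not inferences — sensitivity of the
univariate hazard ratios to imputation can be checked by running the
screen on complete cases versus imputed data.

## Univariate screening

Each clinical covariate and each miRNA is screened with a one-covariate
Cox model: Efron tie handling, Wald 95% CIs (`exp(β̂ ± 1.96·SE)`) and
two-sided Wald p-values. Categorical covariates expand to dummies against
fixed reference levels (stage I, female, never-smoker, no treatment);
stage is 3-level (I/II/IIIA) by default with a 5-level option. A
monotone-likelihood fit (perfect separation) yields a flagged row with an
infinite CI bound instead of an exception. The Benjamini–Hochberg step-up
procedure at level δ (default 0.05) is applied to the miRNA p-values
only: sort ascending, critical value `(j/m)·δ`, reject tests 1..j* where
j* is the largest j with `p(j) ≤ (j/m)·δ`; ties keep input order.
Descriptive output includes Kaplan–Meier curves with log-log (Greenwood)
CIs, the median survival time (earliest time the curve reaches 0.5;
"not reached" when it never does), the log-rank test between groups, and
the median follow-up computed as the median time at risk of censored
patients (mean-of-middle-two for even counts).

## The combined model

The multivariable model is an elastic-net Cox regression over all miRNAs
with **unpenalized** clinical covariates (disease stage by default,
penalty factor 0):

* mixing parameter α = 0.5 (between lasso selection and ridge shrinkage,
  chosen for correlated predictors);
* miRNA columns standardized internally to mean 0, SD 1, so the penalty
  and the selection cap are scale-free; coefficients are mapped back to
  the −ΔCT scale for reporting;
* a geometric path of 100 λ values from the data-derived λ_max down to
  0.01·λ_max, **truncated before the first λ at which more than 5
  penalized variables would be active** — the cap is implemented as path
  truncation (the standard device in penalized-path software), never
  post-hoc deletion, and clinical covariates never count against it;
* λ chosen on the admissible path by 10-fold cross-validated
  partial-likelihood deviance (Verweij–van Houwelingen:
  `−2·[pl(β_−k; all) − pl(β_−k; train_k)]` per fold), folds stratified by
  event status and reproducible from a seed; the minimum-deviance λ is
  used (no 1-SE rule), ties going to the larger λ.

Coordinate-descent path fitting is delegated to scikit-survival's Coxnet
(Breslow ties); the truncation, CV deviance and selection logic are this
package's. The prognostic index (PI) of a patient is the linear predictor
x'β — no baseline hazard is needed for ranking, grouping or ROC analysis.

## Internal validation

Validation follows the cross-validated resampling scheme used for
high-dimensional survival classifiers:

* **LOOCV prognostic indices.** For each patient the *entire* modelling
  procedure — standardization, path construction, inner 10-fold λ search
  — is refit on the other n−1 patients (re-seeded deterministically per
  left-out patient), and the held-out patient is scored by that model.
  No statistic of the held-out patient enters the fit that scores them.
* **Risk groups.** Patients split at the median cross-validated PI;
  values exactly at the median go to the low-risk group (so with odd n
  the low group is larger). K–M curves per group and the log-rank
  chi-square summarize separation. An all-equal PI vector is refused as
  a degenerate classifier, as is a split that leaves a single group.
* **Time-dependent ROC.** At a landmark t* (default 24 months — two-year
  relapse is the clinically salient horizon; configurable), cases are
  patients with an observed event by t*, controls those event-free beyond
  t*. The cumulative/dynamic ROC uses inverse-probability-of-censoring
  weights from the Kaplan–Meier estimate of the censoring distribution
  (cases weighted 1/G(T−); the constant control weight cancels). The AUC
  is the weighted case-control concordance with ties counting 1/2,
  identical to the trapezoid area under the weighted curve, and matches
  the established IPCW estimator in scikit-survival.
* **Permutation tests**, all with the +1 convention
  `p = (1 + #{perm ≥ obs}) / (B_ok + 1)` so p is never 0 and failed
  permutations shrink the denominator:
  1. *Outcome shuffling*: the (time, event) pairs are permuted against
     the joint (miRNA, clinical) rows and the full pipeline — LOOCV
     included — reruns per permutation; the log-rank statistic's p tests
     risk-group separation, and the same reruns give a two-sided p for
     AUC = 0.5 (via |AUC − ½|). Disease stage stays with the miRNAs by
     default; a flag moves it to the outcome side instead, since either
     reading of "the correspondence between markers and outcome and
     stage" is defensible.
  2. *miRNA reassignment*: only the miRNA block is shuffled, keeping the
     clinical/outcome correspondence intact — the null is that survival
     and clinical covariates are independent of the miRNAs. The observed
     combined-model statistics (log-rank and AUC) are compared to their
     permutation distributions, quantifying the miRNAs' *added* value
     over the clinical-only model, whose own LOOCV statistics are
     reported alongside.

B defaults to 1000 in the run configuration; drivers and the acceptance
script use smaller B (49) and report the resolution 1/(B+1) alongside.

## Synthetic cohorts

The generator draws, per cohort: latent expression
`x_gj = gene_g + sample_j + noise` (two designated stable, well-expressed
targets get a small residual SD so a stability ranking should recover
them); Ct as `intercept − x + tech_j` where the per-sample technical
offset `tech_j` is shared with the spike-in well; disease stage from a
3-simplex; Weibull proportional-hazards event times with linear predictor
`β_stage·stage + Σ β_g·(x_g − gene_g)` (the gene-level term is removed so
a random abundance draw rescales only the baseline hazard, never the
signal); censoring as the minimum of a uniform draw and an administrative
horizon; and below-detection missingness by thresholding Ct at the
detection limit (35 cycles by default), with an optional independent
Bernoulli (MCAR) mode for imputation fixtures. DFS and OS share the
linear predictor but use independent baseline draws (OS with a longer
scale); their orderings are not linked patient by patient. Time is in
months. Defaults mirror an early-stage surgical cohort: ~83 patients per
histotype, stage mix ~51/32/17%, event fractions near three-quarters for
DFS over a long follow-up.

What the generator does *not* emulate: correlated miRNA co-expression
modules, amplification-efficiency differences between assays,
batch/plate effects, informative censoring, or any marginal matching to a
real cohort beyond the configurable stage frequencies. Passing tests
therefore demonstrate the correctness and calibration of the *procedure*,
not the reproduction of any particular cohort's estimates.

## Numerical choices and scale decisions

* Breslow ties in the penalized fit and its CV deviance (matching the
  path solver); Efron ties in all lifelines-based fits — simulated times
  are continuous, where the two coincide.
* Master seed fan-out uses `numpy.random.SeedSequence` over (seed, stage
  tag, replicate index), so serial and parallel execution, or re-running
  one stage, agree bit for bit.
* Degenerate situations fail loudly and specifically: a single patient at
  spike-in centring, fewer than three complete stability candidates
  (naming the dropped genes), a masked reference (naming patients), fewer
  events than folds, constant PIs, an empty ROC case or control set.
* Resampling checks in the test suite run at reduced scale — null
  cohorts of 24 patients with 6 miRNAs, a 25-λ path capped at 3, B = 19,
  40 replicates for type-I calibration; 60 patients and 10 miRNAs for the
  added-value power check — sizes chosen so the whole suite runs on one
  CPU in minutes while each Monte-Carlo bound scales with its own
  replicate count. The acceptance script uses the full 83-patient,
  84-target geometry with B = 49.

## Known limitations

* The stability score is this package's definition (documented above);
  published reference-selection tools implement related but not identical
  estimators, so selected references can differ on borderline data.
* The 5-variable cap reads "variables" as penalized (miRNA) variables;
  stage dummies are unpenalized and never count. The alternative reading
  would cap total model size instead.
* Single-landmark ROC only; no integrated (time-averaged) AUC, no
  confidence bands for the cross-validated AUC beyond the permutation p.
* No multiple imputation or EM-based imputation; no competing risks; no
  stage-stratified baseline hazards.
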