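"""End-to-end orchestration: simulate/load → normalize → QC → screen →
fit → validate, separately per histotype and per endpoint (never pooled).

A single :class:`RunConfig` (typically loaded from YAML) drives the whole
run; one master seed fans out deterministically to every stochastic stage
(see :mod:`mirsurv._seeds`), so rerunning with the same configuration
yields byte-identical JSON/CSV artifacts apart from the manifest's wall
time.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from ._seeds import TAG_SIMULATE, child_seed
from .datatypes import CtPlate, ExpressionMatrix
from .missing import exclude_sparse, knn_impute, test_differential_missingness
from .normalization import delta_ct, rank_stability, spikein_center
from .penalized import ModelConfig, fit_elastic_net_cox
from .simulate import SimulationConfig, simulate_cohort
from .screen import median_followup, screen_clinical, screen_mirnas
from .validation import validate_model

log = logging.getLogger("mirsurv")


class StageFailure(RuntimeError):
    """A pipeline stage failed; partial artifacts are kept on disk."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one analysis run needs, with the standard defaults."""

    plate_path: str | None = None
    clinical_path: str | None = None
    simulate: SimulationConfig | None = None
    histotypes: tuple[str, ...] = ("SCC",)
    endpoints: tuple[str, ...] = ("DFS", "OS")
    exclusion_threshold: float = 0.5
    fdr_delta: float = 0.05
    knn_k: int = 5
    alpha: float = 0.5
    max_selected: int = 5
    folds: int = 10
    t_star: float = 24.0
    n_permutations: int = 1000
    seed: int = 0
    outdir: str = "results/run"

    def model_config(self) -> ModelConfig:
        return ModelConfig(alpha=self.alpha, max_selected=self.max_selected,
                           folds=self.folds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("prognostic_set", "beta_mirna", "beta_stage",
                        "stage_probs", "stable_set", "low_expression_set"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulate = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _load_inputs(config: RunConfig) -> tuple[CtPlate, pd.DataFrame]:
    if config.simulate is not None:
        plate, clinical, _ = simulate_cohort(config.simulate)
        return plate, clinical
    if not (config.plate_path and config.clinical_path):
        raise ValueError("config needs either a simulate block or both "
                         "plate_path and clinical_path")
    plate = io.read_plate(config.plate_path)
    clinical = io.read_clinical(config.clinical_path)
    io.check_id_alignment(plate, clinical)
    return plate, clinical


def analyze_cohort(plate: CtPlate, clinical: pd.DataFrame, endpoint: str,
                   config: RunConfig, outdir: Path, seed: int) -> dict:
    """The per-histotype, per-endpoint analysis chain; writes artifacts
    under ``outdir`` and returns a summary dict."""
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {"n_patients": plate.n_patients,
                    "n_targets_on_plate": len(plate.target_ids)}

    stage = "normalize:spikein"
    try:
        centered = spikein_center(plate)

        stage = "qc:exclude_sparse"
        kept_plate, excl_report = exclude_sparse(centered,
                                                 config.exclusion_threshold)
        excl_report.summary.to_csv(outdir / "missingness_exclusion.csv",
                                   index=False)
        counts["n_excluded_sparse"] = len(excl_report.excluded_gene_ids)

        stage = "qc:differential_missingness"
        diff = test_differential_missingness(kept_plate, clinical, endpoint)
        diff.summary.to_csv(outdir / "missingness_tests.csv", index=False)

        stage = "normalize:rank_stability"
        ranking = rank_stability(kept_plate)
        ranking.to_frame().to_csv(outdir / "stability_ranking.csv", index=False)
        counts["selected_references"] = list(ranking.selected_references)

        stage = "impute:knn"
        imputed = knn_impute(kept_plate, k=config.knn_k)
        io.write_imputation_audit(kept_plate, imputed,
                                  outdir / "imputed_cells.csv")

        stage = "normalize:delta_ct"
        expr = delta_ct(imputed, ranking)
        io.write_expression(expr, outdir / "expression_neg_delta_ct.csv")
        counts["n_mirnas_analyzed"] = len(expr.mirna_ids)

        stage = "screen"
        clin_tab = screen_clinical(clinical, endpoint)
        clin_tab.to_csv(outdir / "screen_clinical.csv", index=False)
        mirna_tab = screen_mirnas(expr, clinical, endpoint,
                                  delta=config.fdr_delta)
        mirna_tab.to_csv(outdir / "screen_mirnas.csv", index=False)
        from .datatypes import endpoint_columns
        tcol, ecol = endpoint_columns(endpoint)
        counts["n_events"] = int(clinical[ecol].sum())
        counts["median_followup_months"] = median_followup(
            clinical[tcol].to_numpy(), clinical[ecol].to_numpy())

        stage = "fit:elastic_net"
        fit = fit_elastic_net_cox(expr, clinical, endpoint,
                                  config=config.model_config(),
                                  seed=child_seed(seed, 1))
        io.write_json(fit.to_dict(), outdir / "penalized_fit.json")
        fit.coefficient_table().to_csv(outdir / "penalized_coefficients.csv",
                                       index=False)
        counts["selected_mirnas"] = fit.selected_mirnas

        stage = "validate"
        report = validate_model(expr, clinical, endpoint,
                                model_config=config.model_config(),
                                B=config.n_permutations, t_star=config.t_star,
                                seed=child_seed(seed, 2))
        io.write_json(report.to_dict(), outdir / "validation_report.json")
        report.cv_roc.to_csv(outdir / "cv_roc_curve.csv", index=False)
        km_rows = []
        for grp, curve in report.cv_km.curves.items():
            c = curve.copy()
            c.insert(0, "group", grp)
            km_rows.append(c)
        pd.concat(km_rows).to_csv(outdir / "cv_km_curves.csv", index=False)
        counts["cv_auc"] = report.cv_auc
        counts["p_logrank_perm"] = report.p_logrank_perm
    except Exception as exc:                       # noqa: BLE001
        log.error("stage %s failed: %s", stage, exc)
        raise StageFailure(stage, exc) from exc
    return counts


def run_pipeline(config: RunConfig) -> dict:
    """Run every histotype × endpoint analysis; returns the manifest."""
    t0 = time.time()
    outroot = Path(config.outdir)
    outroot.mkdir(parents=True, exist_ok=True)
    plate, clinical = _load_inputs(config)
    manifest: dict = {"config": config.to_dict(), "cohorts": {}}

    for hi, histotype in enumerate(config.histotypes):
        cl_h = clinical[clinical["histotype"] == histotype].reset_index(drop=True)
        if cl_h.empty:
            log.warning("no patients with histotype %s; skipped", histotype)
            continue
        plate_h = plate.subset_patients(cl_h["patient_id"].tolist())
        for ei, endpoint in enumerate(config.endpoints):
            key = f"{histotype}_{endpoint}"
            log.info("analyzing %s: %d patients", key, len(cl_h))
            counts = analyze_cohort(
                plate_h, cl_h, endpoint, config,
                outroot / histotype / endpoint,
                seed=child_seed(config.seed, hi, ei))
            log.info("%s: %s", key, counts)
            manifest["cohorts"][key] = counts

    import mirsurv
    manifest["versions"] = {"mirsurv": mirsurv.__version__,
                            "numpy": np.__version__,
                            "pandas": pd.__version__}
    manifest["wall_time_s"] = round(time.time() - t0, 2)
    manifest["seed"] = config.seed
    io.write_json(manifest, outroot / "manifest.json")
    return manifest
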