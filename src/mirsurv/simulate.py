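"""Synthetic serum-miRNA qPCR cohorts with proportional-hazards outcome.

The generator emulates the two inputs of the analysis — a Ct plate from a
serum miRNA qPCR array (84 targets, 6 housekeeping snRNAs, one exogenous
spike-in per patient) and a clinical table with staging, treatment and two
right-censored endpoints (DFS, OS) — with the statistical structure the
downstream stages assume:

* additive latent expression ``x_gj = gene_g + sample_j + noise``, with two
  designated low-residual ("stable") targets that a stability ranking
  should recover as reference genes;
* Ct as an affine map of ``−x`` plus a per-sample technical offset shared
  with the spike-in well, so spike-in centring removes it;
* Weibull proportional-hazards event times with a linear predictor on
  disease stage and a small set of prognostic targets;
* right censoring (uniform + administrative) and below-detection
  missingness by thresholding Ct, plus an optional MCAR mode for
  imputation fixtures.

Everything is reproducible from ``SimulationConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import CtPlate, DEFAULT_HOUSEKEEPING, validate_clinical


class SimulationError(RuntimeError):
    """Raised when the generator produces non-finite draws."""


def _default_target_ids(n: int) -> list[str]:
    return [f"miR-sim-{i+1:03d}" for i in range(n)]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated histotype cohort.

    Defaults mirror an early-stage NSCLC surgical cohort followed for
    years: ~83 patients per histotype, stage mix dominated by stage I,
    months as the time unit, administrative censoring at the follow-up
    horizon, and a detection limit of 35 cycles.
    """

    n_patients: int = 83
    n_targets: int = 84
    n_housekeeping: int = 6

    # prognostic structure
    prognostic_set: tuple[int, ...] = ()
    beta_mirna: tuple[float, ...] = ()          # per unit of −ΔCT
    beta_stage: tuple[float, float] = (0.60, 1.23)  # stage II, IIIA vs I
    stage_probs: tuple[float, float, float] = (0.51, 0.32, 0.17)

    # baseline hazard and censoring (months)
    weibull_shape: float = 1.1
    weibull_scale: float = 55.0
    censor_admin_time: float = 150.0
    censor_uniform_max: float = 170.0
    os_scale_factor: float = 1.4

    # Ct model
    detection_limit_ct: float = 35.0
    sigma_gene: float = 2.5
    sigma_sample: float = 1.0
    sigma_noise: float = 1.0
    ref_noise_sd: float = 0.05
    stable_set: tuple[int, int] = (0, 1)
    stable_abundance_shift: float = 3.0   # references are well-expressed
    low_expression_set: tuple[int, ...] = ()
    low_expression_shift: float = 9.0
    mcar_prob: float = 0.0
    ct_intercept: float = 29.0
    spikein_mean_ct: float = 24.0
    spikein_sd: float = 0.8

    histotype: str = "SCC"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.stage_probs) - 1.0) > 1e-12:
            raise ValueError("stage_probs must sum to 1 within 1e-12")
        for name in ("sigma_gene", "sigma_sample", "sigma_noise",
                     "ref_noise_sd", "spikein_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("weibull_shape and weibull_scale must be > 0")
        if len(self.prognostic_set) != len(set(self.prognostic_set)):
            raise ValueError("prognostic_set indices must be distinct")
        if any(not (0 <= i < self.n_targets) for i in self.prognostic_set):
            raise ValueError("prognostic_set indices out of range")
        if len(self.beta_mirna) != len(self.prognostic_set):
            raise ValueError("beta_mirna must align with prognostic_set")
        if not (0.0 <= self.mcar_prob < 1.0):
            raise ValueError("mcar_prob must be in [0, 1)")


@dataclass
class Truth:
    """Ground truth recorded alongside a simulated cohort."""

    latent_expression: pd.DataFrame      # patients × targets, −ΔCT-like scale
    linear_predictor: np.ndarray         # per-patient log hazard contribution
    beta_mirna_full: np.ndarray          # length n_targets, zeros off support
    beta_stage: tuple[float, float]
    stable_ids: tuple[str, str]
    prognostic_ids: tuple[str, ...]
    config: SimulationConfig

    def to_json(self) -> str:
        payload = {
            "linear_predictor": self.linear_predictor.tolist(),
            "beta_mirna_full": self.beta_mirna_full.tolist(),
            "beta_stage": list(self.beta_stage),
            "stable_ids": list(self.stable_ids),
            "prognostic_ids": list(self.prognostic_ids),
            "latent_expression": self.latent_expression.to_dict(orient="list"),
            "config": asdict(self.config),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def simulate_cohort(config: SimulationConfig) -> tuple[CtPlate, pd.DataFrame, Truth]:
    """Draw one cohort: Ct plate, clinical table and the generating truth."""
    rng = np.random.default_rng(config.seed)
    n, p, h = config.n_patients, config.n_targets, config.n_housekeeping
    g = p + h

    target_ids = _default_target_ids(p)
    hk_ids = list(DEFAULT_HOUSEKEEPING[:h]) + [
        f"snRNA-sim-{i+1}" for i in range(max(0, h - len(DEFAULT_HOUSEKEEPING)))
    ]
    patient_ids = [f"P{config.histotype}{i+1:04d}" for i in range(n)]

    # latent expression: gene + sample + noise
    gene_eff = rng.normal(0.0, config.sigma_gene, size=g)
    gene_eff[list(config.low_expression_set)] -= config.low_expression_shift
    gene_eff[list(config.stable_set)] = (
        np.abs(gene_eff[list(config.stable_set)]) + config.stable_abundance_shift)
    sample_eff = rng.normal(0.0, config.sigma_sample, size=n)
    noise_sd = np.full(g, config.sigma_noise)
    noise_sd[list(config.stable_set)] = config.ref_noise_sd
    noise = rng.normal(0.0, 1.0, size=(n, g)) * noise_sd[None, :]
    x = gene_eff[None, :] + sample_eff[:, None] + noise   # (n, g)

    # technical per-sample offset, shared by every well incl. the spike-in
    tech = rng.normal(0.0, config.spikein_sd, size=n)
    spikein_ct = config.spikein_mean_ct + tech
    ct = config.ct_intercept - x + tech[:, None]

    # clinical covariates
    stage = rng.choice(np.array(["I", "II", "IIIA"]), size=n, p=config.stage_probs)
    age = rng.normal(68.0, 8.0, size=n)
    gender = rng.choice(np.array(["female", "male"]), size=n, p=[0.25, 0.75])
    smoking = rng.choice(np.array(["never", "ex", "current"]), size=n,
                         p=[0.15, 0.30, 0.55])
    chemo = rng.random(n) < 0.16
    radio = rng.random(n) < 0.12

    # proportional-hazards linear predictor on stage and prognostic targets
    beta_full = np.zeros(p)
    for idx, b in zip(config.prognostic_set, config.beta_mirna):
        beta_full[idx] = b
    b2, b3 = config.beta_stage
    # the hazard acts on expression relative to the gene's cohort level, so
    # a random gene-abundance draw rescales nothing but the baseline
    eta = (x[:, :p] - gene_eff[None, :p]) @ beta_full + \
        np.where(stage == "II", b2, 0.0) + np.where(stage == "IIIA", b3, 0.0)

    def _draw_endpoint(scale: float) -> tuple[np.ndarray, np.ndarray]:
        u = rng.uniform(size=n)
        t_event = scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / config.weibull_shape)
        c_unif = (rng.uniform(0.0, config.censor_uniform_max, size=n)
                  if np.isfinite(config.censor_uniform_max)
                  else np.full(n, np.inf))
        c = np.minimum(c_unif, config.censor_admin_time)
        time = np.minimum(t_event, c)
        event = t_event <= c
        return time, event

    dfs_time, dfs_event = _draw_endpoint(config.weibull_scale)
    os_time, os_event = _draw_endpoint(config.weibull_scale * config.os_scale_factor)

    if not (np.all(np.isfinite(ct)) and np.all(np.isfinite(dfs_time))
            and np.all(np.isfinite(os_time)) and np.all(dfs_time > 0)
            and np.all(os_time > 0)):
        raise SimulationError(f"non-finite draws with config {config!r}")

    # below-detection thresholding; optional independent MCAR masking
    undet = ct > config.detection_limit_ct
    if config.mcar_prob > 0.0:
        undet |= rng.random((n, g)) < config.mcar_prob

    plate = CtPlate(
        patient_ids=patient_ids,
        target_ids=target_ids,
        housekeeping_ids=hk_ids,
        spikein_ct=spikein_ct,
        ct=ct,
        undetermined=undet,
    )

    clinical = pd.DataFrame({
        "patient_id": patient_ids,
        "histotype": config.histotype,
        "stage": stage,
        "age_at_surgery": np.round(age, 1),
        "gender": gender,
        "smoking": smoking,
        "chemo": chemo,
        "radio": radio,
        "dfs_time": dfs_time,
        "dfs_event": dfs_event,
        "os_time": os_time,
        "os_event": os_event,
    })
    validate_clinical(clinical)

    truth = Truth(
        latent_expression=pd.DataFrame(x[:, :p], columns=target_ids,
                                       index=patient_ids),
        linear_predictor=eta,
        beta_mirna_full=beta_full,
        beta_stage=config.beta_stage,
        stable_ids=(target_ids[config.stable_set[0]], target_ids[config.stable_set[1]]),
        prognostic_ids=tuple(target_ids[i] for i in config.prognostic_set),
        config=config,
    )
    return plate, clinical, truth
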