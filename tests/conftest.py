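"""Shared fixtures: all data are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirsurv.datatypes import CtPlate
from mirsurv.simulate import SimulationConfig, simulate_cohort

# property tests assert exact invariances; derandomize for repeatable runs
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_plate(ct: np.ndarray, undetermined: np.ndarray | None = None,
               spikein: np.ndarray | None = None,
               n_housekeeping: int = 0, centered: bool = False,
               gene_ids: list[str] | None = None) -> CtPlate:
    """Hand-built plate for arithmetic fixtures."""
    ct = np.asarray(ct, dtype=float)
    n, g = ct.shape
    if undetermined is None:
        undetermined = np.zeros_like(ct, dtype=bool)
    if spikein is None:
        spikein = np.full(n, 24.0)
    p = g - n_housekeeping
    if gene_ids is None:
        gene_ids = [f"g{j:02d}" for j in range(g)]
    return CtPlate(
        patient_ids=[f"pt{i:02d}" for i in range(n)],
        target_ids=gene_ids[:p],
        housekeeping_ids=gene_ids[p:],
        spikein_ct=np.asarray(spikein, dtype=float),
        ct=ct,
        undetermined=np.asarray(undetermined, dtype=bool),
        spikein_centered=centered,
    )


@pytest.fixture(scope="session")
def signal_cohort():
    """Medium cohort with three prognostic miRNAs, stage effects and
    planted sparse genes — shared by the heavier integration tests."""
    cfg = SimulationConfig(
        n_patients=60, n_targets=30, n_housekeeping=4,
        prognostic_set=(5, 6, 7), beta_mirna=(0.7, -0.7, 0.7),
        low_expression_set=(20, 21, 22), low_expression_shift=12.0,
        detection_limit_ct=37.0, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no miRNA or stage signal (global null)."""
    cfg = SimulationConfig(
        n_patients=60, n_targets=20, n_housekeeping=4,
        beta_stage=(0.0, 0.0), detection_limit_ct=45.0, seed=19)
    return simulate_cohort(cfg)
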