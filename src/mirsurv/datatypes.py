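"""Core data containers: qPCR Ct plates, clinical tables, expression matrices.

A :class:`CtPlate` holds raw (or spike-in-centred) Ct values for target
miRNAs and housekeeping snRNAs, one row per patient, together with the
boolean ``undetermined`` mask marking wells that never crossed the
fluorescence threshold.  Masked cells carry ``NaN`` — they have no value.

The clinical table is a plain :class:`pandas.DataFrame` with a documented
schema (see :data:`CLINICAL_COLUMNS`); :func:`validate_clinical` enforces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Spike-in control added at RNA extraction; a per-patient technical anchor.
SPIKEIN_ID = "cel-miR-39"

#: The six snRNA housekeeping wells of a serum/plasma miRNA qPCR array.
DEFAULT_HOUSEKEEPING = (
    "SNORD61", "SNORD68", "SNORD72", "SNORD95", "SNORD96A", "RNU6-2",
)

CLINICAL_COLUMNS = (
    "patient_id", "histotype", "stage", "age_at_surgery", "gender",
    "smoking", "chemo", "radio",
    "dfs_time", "dfs_event", "os_time", "os_event",
)

STAGE_LEVELS = ("I", "II", "IIIA")
HISTOTYPES = ("SCC", "ADC")
ENDPOINTS = ("DFS", "OS")


class PlateError(ValueError):
    """Structural problem with a Ct plate."""


@dataclass
class CtPlate:
    """Per-patient Ct values for target and housekeeping wells.

    ``ct`` is ``(n_patients, n_targets + n_housekeeping)`` with target
    columns first.  ``undetermined`` is aligned to ``ct``; wherever it is
    True the corresponding ``ct`` cell is NaN.  ``spikein_ct`` must be
    finite for every patient: a missing spike-in is an extraction failure,
    not a missing value.
    """

    patient_ids: list[str]
    target_ids: list[str]
    housekeeping_ids: list[str]
    spikein_ct: np.ndarray
    ct: np.ndarray
    undetermined: np.ndarray
    spikein_centered: bool = False

    def __post_init__(self) -> None:
        self.spikein_ct = np.asarray(self.spikein_ct, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        self.undetermined = np.asarray(self.undetermined, dtype=bool)
        n = len(self.patient_ids)
        g = len(self.target_ids) + len(self.housekeeping_ids)
        if self.ct.shape != (n, g):
            raise PlateError(f"ct shape {self.ct.shape} != ({n}, {g})")
        if self.undetermined.shape != self.ct.shape:
            raise PlateError("undetermined mask not aligned to ct")
        if len(set(self.patient_ids)) != n:
            raise PlateError("duplicate patient ids")
        if len(set(self.gene_ids)) != g:
            raise PlateError("duplicate gene ids")
        if not np.all(np.isfinite(self.spikein_ct)):
            bad = [p for p, ok in zip(self.patient_ids, np.isfinite(self.spikein_ct)) if not ok]
            raise PlateError(f"non-finite spike-in Ct for patients: {bad}")
        if not np.all(np.isfinite(self.ct[~self.undetermined])):
            raise PlateError("non-finite Ct in unmasked cells")
        # normalise: masked cells carry no value
        self.ct = self.ct.copy()
        self.ct[self.undetermined] = np.nan

    @property
    def gene_ids(self) -> list[str]:
        return list(self.target_ids) + list(self.housekeeping_ids)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not on plate") from None

    def column(self, gene_id: str) -> np.ndarray:
        return self.ct[:, self.gene_index(gene_id)]

    def copy(self) -> "CtPlate":
        return replace(
            self,
            patient_ids=list(self.patient_ids),
            target_ids=list(self.target_ids),
            housekeeping_ids=list(self.housekeeping_ids),
            spikein_ct=self.spikein_ct.copy(),
            ct=self.ct.copy(),
            undetermined=self.undetermined.copy(),
        )

    def subset_genes(self, keep_target_ids: Sequence[str]) -> "CtPlate":
        """Plate restricted to the given target genes (housekeeping kept)."""
        keep = set(keep_target_ids)
        idx = [i for i, t in enumerate(self.target_ids) if t in keep]
        cols = idx + list(range(len(self.target_ids), self.ct.shape[1]))
        return replace(
            self,
            target_ids=[self.target_ids[i] for i in idx],
            ct=self.ct[:, cols].copy(),
            undetermined=self.undetermined[:, cols].copy(),
        )

    def subset_patients(self, keep_patient_ids: Sequence[str]) -> "CtPlate":
        keep = set(keep_patient_ids)
        rows = [i for i, p in enumerate(self.patient_ids) if p in keep]
        return replace(
            self,
            patient_ids=[self.patient_ids[i] for i in rows],
            spikein_ct=self.spikein_ct[rows].copy(),
            ct=self.ct[rows].copy(),
            undetermined=self.undetermined[rows].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per patient; spike-in first, then targets, housekeeping."""
        df = pd.DataFrame(self.ct, columns=self.gene_ids)
        df.insert(0, SPIKEIN_ID, self.spikein_ct)
        df.insert(0, "patient_id", self.patient_ids)
        return df


@dataclass
class ExpressionMatrix:
    """Normalised expression on the −ΔCT scale (patients × miRNAs).

    Higher values mean higher abundance.  The two selected reference genes
    and all housekeeping wells are absent by construction.
    """

    patient_ids: list[str]
    mirna_ids: list[str]
    value: np.ndarray

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != (len(self.patient_ids), len(self.mirna_ids)):
            raise ValueError("value shape does not match ids")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.value, columns=self.mirna_ids)
        df.insert(0, "patient_id", self.patient_ids)
        return df


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical-table schema and value domains.

    Returns the (unmodified) frame so the call can be chained.  Missing
    covariate values are permitted; times must be positive where present,
    and event indicators boolean-like.  DFS and OS are independent
    endpoints: ``os_time >= dfs_time`` is deliberately not enforced.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required columns: {missing}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids: {dup}")
    bad_hist = set(df["histotype"].dropna()) - set(HISTOTYPES)
    if bad_hist:
        raise ValueError(f"unknown histotype levels: {sorted(bad_hist)}")
    bad_stage = set(df["stage"].dropna()) - {"I", "IA", "IB", "II", "IIA", "IIB", "IIIA"}
    if bad_stage:
        raise ValueError(f"unknown stage levels: {sorted(bad_stage)}")
    for tcol in ("dfs_time", "os_time"):
        t = pd.to_numeric(df[tcol], errors="coerce")
        if (t.dropna() <= 0).any():
            raise ValueError(f"{tcol} must be > 0")
    return df


def endpoint_columns(endpoint: str) -> tuple[str, str]:
    """Map an endpoint name ('DFS'/'OS') to its (time, event) columns."""
    ep = endpoint.upper()
    if ep not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")
    return (f"{ep.lower()}_time", f"{ep.lower()}_event")


def coarse_stage(stage: pd.Series) -> pd.Series:
    """Collapse a 5-level stage (IA/IB/IIA/IIB/IIIA) to 3 levels (I/II/IIIA)."""
    mapping = {"IA": "I", "IB": "I", "IIA": "II", "IIB": "II",
               "I": "I", "II": "II", "IIIA": "IIIA"}
    return stage.map(mapping)
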