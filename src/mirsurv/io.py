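"""Tabular file formats for plates, clinical tables and reports.

Plate CSV dialect: one row per patient; columns ``patient_id``, the
spike-in well (``cel-miR-39``), then one column per gene.  Undetermined
wells are written with the sentinel ``Undetermined`` and parsed
case-insensitively (an empty cell also counts as masked).  Housekeeping
columns are recognised by name (the standard snRNA panel) unless given
explicitly.  Round-trips are stable: write∘read is the identity on values
and masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (CLINICAL_COLUMNS, DEFAULT_HOUSEKEEPING, SPIKEIN_ID,
                        CtPlate, ExpressionMatrix, validate_clinical)

UNDETERMINED_SENTINEL = "Undetermined"


def write_plate(plate: CtPlate, path: str | Path) -> None:
    df = plate.to_frame()
    for gid in plate.gene_ids:
        col = df[gid].astype(object)
        mask = plate.undetermined[:, plate.gene_index(gid)]
        col[mask] = UNDETERMINED_SENTINEL
        df[gid] = col
    df.to_csv(path, index=False)


def read_plate(path: str | Path,
               housekeeping_ids: list[str] | None = None,
               spikein_centered: bool = False) -> CtPlate:
    """Parse a plate CSV; raises with row numbers on malformed cells."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns:
        raise ValueError("plate file missing required column 'patient_id'")
    if SPIKEIN_ID not in df.columns:
        raise ValueError(f"plate file missing spike-in column {SPIKEIN_ID!r}")
    gene_cols = [c for c in df.columns if c not in ("patient_id", SPIKEIN_ID)]
    if housekeeping_ids is None:
        housekeeping_ids = [c for c in gene_cols if c in DEFAULT_HOUSEKEEPING
                            or c.startswith("snRNA-")]
    target_ids = [c for c in gene_cols if c not in housekeeping_ids]

    n = len(df)
    ct = np.full((n, len(gene_cols)), np.nan)
    undet = np.zeros((n, len(gene_cols)), dtype=bool)
    ordered = target_ids + list(housekeeping_ids)
    for j, gid in enumerate(ordered):
        for i, raw in enumerate(df[gid].astype(str)):
            s = raw.strip()
            if s == "" or s.lower() == UNDETERMINED_SENTINEL.lower():
                undet[i, j] = True
                continue
            try:
                ct[i, j] = float(s)
            except ValueError:
                raise ValueError(
                    f"malformed Ct value {raw!r} at row {i + 2}, "
                    f"column {gid!r} of {path}") from None
    try:
        spikein = df[SPIKEIN_ID].astype(float).to_numpy()
    except ValueError:
        bad = [i + 2 for i, v in enumerate(df[SPIKEIN_ID])
               if not v.strip().replace(".", "", 1).lstrip("+-").isdigit()]
        raise ValueError(f"non-numeric spike-in Ct at rows {bad} of {path}") from None
    return CtPlate(patient_ids=df["patient_id"].tolist(),
                   target_ids=target_ids,
                   housekeeping_ids=list(housekeeping_ids),
                   spikein_ct=spikein, ct=ct, undetermined=undet,
                   spikein_centered=spikein_centered)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical file {path} missing columns: {missing}")
    for col in ("chemo", "radio", "dfs_event", "os_event"):
        df[col] = df[col].astype(bool)
    return validate_clinical(df)


def check_id_alignment(plate: CtPlate, clinical: pd.DataFrame) -> None:
    """Plate and clinical table must describe the same patients."""
    p, c = set(plate.patient_ids), set(clinical["patient_id"])
    if p != c:
        raise ValueError(
            "plate/clinical patient id mismatch; only in plate: "
            f"{sorted(p - c)}; only in clinical: {sorted(c - p)}")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, index=False)


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path)
    mirna_ids = [c for c in df.columns if c != "patient_id"]
    return ExpressionMatrix(patient_ids=df["patient_id"].astype(str).tolist(),
                            mirna_ids=mirna_ids,
                            value=df[mirna_ids].to_numpy(dtype=float))


def write_imputation_audit(before: CtPlate, after: CtPlate,
                           path: str | Path) -> None:
    """Sidecar marking which cells were imputed (long format)."""
    rows = []
    filled = before.undetermined & ~after.undetermined
    for i, j in zip(*np.nonzero(filled)):
        rows.append({"patient_id": before.patient_ids[i],
                     "gene": before.gene_ids[j],
                     "imputed_ct": after.ct[i, j]})
    pd.DataFrame(rows, columns=["patient_id", "gene", "imputed_ct"]).to_csv(
        path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
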