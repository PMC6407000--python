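"""Below-detection handling: exclusion, outcome-association tests, KNN imputation.

Wells that never cross the fluorescence threshold ("undetermined") are
treated as missing.  Targets undetermined in more than half of patients
are excluded outright (strict ``> threshold``); for the rest, a per-gene
2×2 test checks whether missingness is associated with the clinical event
(which would make the below-detection mechanism informative), and the
remaining masked cells are filled by a K-nearest-neighbour rule.

The KNN rule: the distance between two patients is the root-mean-square
Ct difference over genes observed in both; the k nearest patients with
the target gene observed contribute an unweighted mean.  All imputations
are computed from the original observed data (not sequentially), so the
operation is deterministic and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CtPlate, endpoint_columns


@dataclass
class MissingnessReport:
    """Per-gene missingness bookkeeping and (optionally) 2×2 test results."""

    summary: pd.DataFrame
    excluded_gene_ids: list[str] = field(default_factory=list)
    threshold: float | None = None
    warning: str | None = None


def exclude_sparse(plate: CtPlate, threshold: float = 0.5) -> tuple[CtPlate, MissingnessReport]:
    """Drop target miRNAs undetermined in a fraction of patients strictly
    greater than ``threshold`` (default 0.5, i.e. ">50%")."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    n = plate.n_patients
    rows = []
    excluded = []
    for gid in plate.target_ids:
        frac = plate.undetermined[:, plate.gene_index(gid)].mean()
        drop = frac > threshold
        if drop:
            excluded.append(gid)
        rows.append({"gene": gid, "n_undetermined": int(round(frac * n)),
                     "fraction_undetermined": frac, "excluded": drop})
    keep = [g for g in plate.target_ids if g not in excluded]
    report = MissingnessReport(summary=pd.DataFrame(rows),
                               excluded_gene_ids=excluded, threshold=threshold)
    if not keep:
        report.warning = "all target miRNAs excluded"
    return plate.subset_genes(keep), report


def _expected_counts(table: np.ndarray) -> np.ndarray:
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    return rowsum * colsum / table.sum()


def test_differential_missingness(plate: CtPlate, clinical: pd.DataFrame,
                                  endpoint: str) -> MissingnessReport:
    """Per gene, test undetermined-status × event-status in a 2×2 table.

    Fisher's exact test when any expected cell count is 5 or below,
    otherwise Pearson's chi-square without continuity correction;
    two-sided p-values.
    Genes never or always undetermined (or a degenerate event margin) are
    recorded as not applicable.
    """
    _, event_col = endpoint_columns(endpoint)
    cl = clinical.set_index("patient_id").loc[plate.patient_ids]
    event = cl[event_col].to_numpy(dtype=bool)
    rows = []
    for gid in plate.target_ids:
        undet = plate.undetermined[:, plate.gene_index(gid)]
        table = np.array([
            [int((undet & event).sum()), int((undet & ~event).sum())],
            [int((~undet & event).sum()), int((~undet & ~event).sum())],
        ])
        degenerate = (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any()
        if degenerate:
            rows.append({"gene": gid, "undet_event": table[0, 0],
                         "undet_noevent": table[0, 1], "det_event": table[1, 0],
                         "det_noevent": table[1, 1], "test": "not_applicable",
                         "statistic": np.nan, "p_value": np.nan})
            continue
        if (_expected_counts(table) <= 5).any():
            res = stats.fisher_exact(table, alternative="two-sided")
            name, stat, p = "fisher", np.nan, res.pvalue
        else:
            chi2 = stats.chi2_contingency(table, correction=False)
            name, stat, p = "chi2", chi2.statistic, chi2.pvalue
        rows.append({"gene": gid, "undet_event": table[0, 0],
                     "undet_noevent": table[0, 1], "det_event": table[1, 0],
                     "det_noevent": table[1, 1], "test": name,
                     "statistic": stat, "p_value": p})
    return MissingnessReport(summary=pd.DataFrame(rows))


def knn_impute(plate: CtPlate, k: int = 5) -> CtPlate:
    """Fill every undetermined cell with the mean of its k nearest donors.

    Distances use the RMS Ct difference over genes observed in both
    patients (infinite if none are shared); donors must have the gene
    observed.  Ties in distance are broken by patient order.  Observed
    cells are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    observed = ~plate.undetermined
    n_obs = observed.sum(axis=0)
    short = [g for g, c in zip(plate.gene_ids, n_obs) if c < k]
    if short:
        raise ValueError(
            f"genes observed in fewer than k={k} patients: {short}; "
            "lower k or exclude these genes first")
    ct = plate.ct
    n = plate.n_patients
    # pairwise RMS distance over shared observed genes
    dist = np.full((n, n), np.inf)
    for i in range(n):
        shared = observed[i][None, :] & observed     # (n, g)
        diff = np.where(shared, ct[i][None, :] - np.where(observed, ct, 0.0), 0.0)
        cnt = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt((diff ** 2).sum(axis=1) / cnt)
        d[cnt == 0] = np.inf
        dist[i] = d
    np.fill_diagonal(dist, np.inf)

    out = plate.copy()
    for j in range(n):
        missing_genes = np.flatnonzero(~observed[j])
        if missing_genes.size == 0:
            continue
        order = np.argsort(dist[j], kind="stable")
        for gcol in missing_genes:
            donors = [i for i in order
                      if observed[i, gcol] and np.isfinite(dist[j, i])][:k]
            if len(donors) < k:
                raise ValueError(
                    f"not enough donors for gene {plate.gene_ids[gcol]!r} "
                    f"patient {plate.patient_ids[j]!r}")
            out.ct[j, gcol] = ct[donors, gcol].mean()
            out.undetermined[j, gcol] = False
    return out
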