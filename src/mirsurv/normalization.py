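"""qPCR normalization: spike-in centring, reference-gene stability, −ΔCT.

The pipeline is the standard serum-miRNA one: first remove per-sample
technical variation using the exogenous spike-in (cel-miR-39), then pick
the two most *stable* endogenous miRNAs as references via a model-based
stability score, and finally subtract the mean reference Ct from every
target well, reporting expression as −ΔCT (higher = more abundant).

The stability score is the residual standard deviation of the additive
two-way model ``ct_gj = gene_g + sample_j + residual_gj`` fitted by
row/column means, with a small-sample factor G/(G−1) applied to the
variance — lower means more stable.  A grouped variant (separating intra-
and inter-group variation, in the spirit of grouped reference-gene
selection tools) is available through ``groups``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import CtPlate, ExpressionMatrix


@dataclass
class StabilityRanking:
    """Genes ordered from most to least stable (ascending score).

    Ties are broken lexicographically by gene id; ``selected_references``
    are the first two entries.
    """

    gene_ids: list[str]
    stability: np.ndarray
    selected_references: tuple[str, str]
    dropped_incomplete: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.gene_ids,
            "stability": self.stability,
            "selected": [g in self.selected_references for g in self.gene_ids],
        })


def spikein_center(plate: CtPlate) -> CtPlate:
    """Subtract each patient's spike-in deviation from every well.

    The offset for patient j is ``spikein_ct_j − mean(spikein_ct)``; it is
    removed from all Ct cells *and* from the spike-in itself, which makes
    the operation idempotent.  Requires at least two patients (the mean of
    a single value is not a centring device).
    """
    if plate.n_patients < 2:
        raise ValueError("spike-in centring needs >= 2 patients")
    offsets = plate.spikein_ct - plate.spikein_ct.mean()
    out = plate.copy()
    out.ct = out.ct - offsets[:, None]
    out.spikein_ct = out.spikein_ct - offsets
    out.spikein_centered = True
    return out


def _two_way_residuals(mat: np.ndarray) -> np.ndarray:
    """Residuals of the additive gene+sample model fitted by means."""
    row = mat.mean(axis=1, keepdims=True)   # per-sample
    col = mat.mean(axis=0, keepdims=True)   # per-gene
    grand = mat.mean()
    return mat - row - col + grand


def _stability_scores(mat: np.ndarray) -> np.ndarray:
    """Per-gene residual SD with the G/(G−1) small-sample variance factor.

    ``mat`` is (patients × genes), complete.
    """
    n_samples, n_genes = mat.shape
    resid = _two_way_residuals(mat)
    var = resid.var(axis=0, ddof=1)
    var = var * n_genes / (n_genes - 1)
    return np.sqrt(var)


def _grouped_stability_scores(mat: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Grouped variant: sqrt(inter-group gene-effect variance + mean
    intra-group residual variance)."""
    labels = np.unique(groups)
    n_genes = mat.shape[1]
    gene_by_group = np.empty((len(labels), n_genes))
    within_var = np.empty((len(labels), n_genes))
    for i, lab in enumerate(labels):
        sub = mat[groups == lab]
        if sub.shape[0] < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
        resid = _two_way_residuals(sub)
        within_var[i] = resid.var(axis=0, ddof=1) * n_genes / (n_genes - 1)
        gene_by_group[i] = sub.mean(axis=0) - sub.mean()
    inter = gene_by_group.var(axis=0, ddof=0)
    return np.sqrt(inter + within_var.mean(axis=0))


def rank_stability(plate: CtPlate, candidate_ids: list[str] | None = None,
                   groups: np.ndarray | None = None) -> StabilityRanking:
    """Rank candidate reference genes by stability (lower = more stable).

    Candidates default to all target miRNAs.  Candidates with *any*
    undetermined value are dropped first; at least three complete
    candidates must remain.  Returns the full ranking and the two
    minimizers (ties broken lexicographically by gene id).
    """
    if candidate_ids is None:
        candidate_ids = list(plate.target_ids)
    cols = [plate.gene_index(gid) for gid in candidate_ids]
    complete = ~plate.undetermined[:, cols].any(axis=0)
    dropped = [gid for gid, ok in zip(candidate_ids, complete) if not ok]
    kept = [gid for gid, ok in zip(candidate_ids, complete) if ok]
    if len(kept) < 3:
        raise ValueError(
            "stability ranking needs >= 3 complete candidates; dropped "
            f"(incomplete): {dropped}")
    mat = plate.ct[:, [plate.gene_index(gid) for gid in kept]]
    if groups is None:
        scores = _stability_scores(mat)
    else:
        scores = _grouped_stability_scores(mat, np.asarray(groups))
    order = sorted(range(len(kept)), key=lambda i: (scores[i], kept[i]))
    gene_ids = [kept[i] for i in order]
    stability = np.array([scores[i] for i in order])
    return StabilityRanking(
        gene_ids=gene_ids,
        stability=stability,
        selected_references=(gene_ids[0], gene_ids[1]),
        dropped_incomplete=dropped,
    )


def delta_ct(plate: CtPlate, refs: StabilityRanking | tuple[str, str]) -> ExpressionMatrix:
    """Subtract the mean reference Ct per patient; report −ΔCT.

    The plate must already be spike-in centred.  Both reference genes must
    be determined in every patient.  Reference columns (and all
    housekeeping wells) are removed from the output; undetermined target
    cells stay NaN.
    """
    if not plate.spikein_centered:
        raise ValueError("plate must be spike-in centred before delta_ct")
    ref_ids = refs.selected_references if isinstance(refs, StabilityRanking) else tuple(refs)
    ref_cols = [plate.gene_index(r) for r in ref_ids]
    masked = plate.undetermined[:, ref_cols].any(axis=1)
    if masked.any():
        bad = [p for p, m in zip(plate.patient_ids, masked) if m]
        raise ValueError(f"reference gene undetermined for patients: {bad}")
    ref_mean = plate.ct[:, ref_cols].mean(axis=1)
    keep = [t for t in plate.target_ids if t not in ref_ids]
    cols = [plate.gene_index(t) for t in keep]
    value = -(plate.ct[:, cols] - ref_mean[:, None])
    return ExpressionMatrix(patient_ids=list(plate.patient_ids),
                            mirna_ids=keep, value=value)
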