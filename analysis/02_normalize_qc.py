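"""Normalize each cohort's plate to −ΔCT expression, with missingness QC.

Steps per histotype: spike-in centring; exclusion of miRNAs undetermined
in >50% of patients; 2×2 tests of missingness against the DFS event;
stability-ranked selection of the two endogenous reference miRNAs (done on
complete, spike-in-centred data); KNN imputation (k = 5) of the remaining
undetermined wells; subtraction of the mean reference Ct.
"""

from pathlib import Path

from mirsurv import io
from mirsurv.missing import exclude_sparse, knn_impute, \
    test_differential_missingness
from mirsurv.normalization import delta_ct, rank_stability, spikein_center

DATA = Path("results/data")
OUT = Path("results/normalized")


def main() -> None:
    for histotype in ("SCC", "ADC"):
        plate = io.read_plate(DATA / histotype / "plate.csv")
        clinical = io.read_clinical(DATA / histotype / "clinical.csv")
        io.check_id_alignment(plate, clinical)

        centered = spikein_center(plate)
        kept, excl = exclude_sparse(centered)
        diff = test_differential_missingness(kept, clinical, "DFS")
        ranking = rank_stability(kept)
        imputed = knn_impute(kept, k=5)
        expr = delta_ct(imputed, ranking)

        outdir = OUT / histotype
        outdir.mkdir(parents=True, exist_ok=True)
        excl.summary.to_csv(outdir / "exclusion.csv", index=False)
        diff.summary.to_csv(outdir / "missingness_tests.csv", index=False)
        ranking.to_frame().to_csv(outdir / "stability_ranking.csv", index=False)
        io.write_imputation_audit(kept, imputed, outdir / "imputed_cells.csv")
        io.write_expression(expr, outdir / "expression.csv")

        n_assoc = int((diff.summary["p_value"] < 0.05).sum())
        print(f"{histotype}: excluded {len(excl.excluded_gene_ids)} sparse "
              f"miRNAs; references {ranking.selected_references}; "
              f"{len(expr.mirna_ids)} miRNAs analyzed; "
              f"{n_assoc} genes with outcome-associated missingness (p<0.05)")


if __name__ == "__main__":
    main()
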