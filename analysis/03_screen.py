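"""Univariate survival screening per histotype and endpoint.

Writes the clinical-covariate table and the per-miRNA screening table
(HR, 95% CI, Wald p, BH rank and critical value at δ = 0.05), plus the
descriptive summaries: median follow-up of censored patients and the
Kaplan–Meier median survival time.
"""

from pathlib import Path

from mirsurv import io
from mirsurv.datatypes import endpoint_columns
from mirsurv.screen import km_summary, median_followup, screen_clinical, \
    screen_mirnas

NORM = Path("results/normalized")
DATA = Path("results/data")
OUT = Path("results/screening")


def main() -> None:
    for histotype in ("SCC", "ADC"):
        expr = io.read_expression(NORM / histotype / "expression.csv")
        clinical = io.read_clinical(DATA / histotype / "clinical.csv")
        for endpoint in ("DFS", "OS"):
            tcol, ecol = endpoint_columns(endpoint)
            outdir = OUT / histotype / endpoint
            outdir.mkdir(parents=True, exist_ok=True)

            clin_tab = screen_clinical(clinical, endpoint)
            clin_tab.to_csv(outdir / "clinical_covariates.csv", index=False)
            mirna_tab = screen_mirnas(expr, clinical, endpoint, delta=0.05)
            mirna_tab.to_csv(outdir / "mirna_screen.csv", index=False)

            km = km_summary(clinical[tcol].to_numpy(),
                            clinical[ecol].to_numpy(dtype=bool))
            med, lo, hi = km.medians["all"]
            fu = median_followup(clinical[tcol].to_numpy(),
                                 clinical[ecol].to_numpy(dtype=bool))
            top = mirna_tab.iloc[0]
            print(f"{histotype}/{endpoint}: median {med:.1f} months "
                  f"(95% CI {lo:.1f}-{hi:.1f}), median follow-up {fu:.1f}; "
                  f"{int(mirna_tab['p_value'].lt(0.05).sum())} miRNAs with "
                  f"p<0.05, {int(mirna_tab['rejected'].sum())} past BH; "
                  f"top hit {top['term']} (HR {top['HR']:.2f}, "
                  f"p={top['p_value']:.5f})")


if __name__ == "__main__":
    main()
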