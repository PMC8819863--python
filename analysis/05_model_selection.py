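"""Fit all 16 biomarker-subset models and run the selection decision tree.

For each population (all / CU / CI) and each Abeta42/40 assay (IP-MS /
Simoa): fit the demographic base plus every subset of {A, G, N, P}, rank by
AIC, LR-test candidates within 2 AIC units of the best, and pick the lowest
BIC among the survivors.  Writes a model-summary table per combination and
the selection audit trail as JSON.
"""

from pathlib import Path

from plasmapet import fit_model_family, select_best_model
from plasmapet.io import read_cohort
from plasmapet.logistic_suite import model_summary_table

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    cohort = read_cohort(OUT / "cohort.csv")
    for assay in ("IP-MS", "Simoa"):
        for population in ("all", "CU", "CI"):
            fits = fit_model_family(cohort, population, assay)
            summary = model_summary_table(fits, reference="demographic")
            tag = f"{population}_{assay.replace('-', '').lower()}"
            summary.to_csv(OUT / f"model_summary_{tag}.tsv", sep="\t")
            sel = select_best_model(fits)
            (OUT / f"selection_{tag}.json").write_text(sel.to_json(indent=2))
            win = fits[sel.selected.name]
            print(
                f"{assay:6s} {population:3s}: selected "
                f"{sel.selected.name or '(demographic)':12s} "
                f"AIC {win.aic:6.1f}  BIC {win.bic:6.1f}  "
                f"AUC {win.roc.auc:.3f} ({win.roc.ci_low:.3f}, {win.roc.ci_high:.3f})"
            )
    print(f"\nwrote model summaries and selection audits under {OUT}")
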