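"""Single-biomarker ROC analysis and the Abeta42/40 assay comparison.

Reports each marker's AUC with DeLong 95% CI for discriminating amyloid-PET
status, and the paired DeLong test between the two Abeta42/40 assays
(IP-MS vs Simoa) on the same participants.
"""

from pathlib import Path

from plasmapet.definitions import BIOMARKER_COLUMNS, BIOMARKERS
from plasmapet.io import read_cohort
from plasmapet.roc_delong import delong_paired_test, roc_report
from plasmapet.synthetic_cohort import abeta_binary

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    cohort = read_cohort(OUT / "cohort.csv")
    labels = abeta_binary(cohort)
    markers = {
        name: (cohort[name].to_numpy(), BIOMARKERS[name].direction)
        for name in BIOMARKER_COLUMNS
    }
    table = roc_report(markers, labels)
    table.to_csv(OUT / "single_biomarker_auc.tsv", sep="\t")
    print(table[["auc", "ci_low", "ci_high"]].round(3).to_string())

    z, p = delong_paired_test(
        cohort["abeta42_40_ipms"], cohort["abeta42_40_simoa"], labels,
        ("lower", "lower"),
    )
    print(f"\nIP-MS vs Simoa Abeta42/40 (paired DeLong): z = {z:.2f}, p = {p:.4g}")
    print(f"wrote {OUT / 'single_biomarker_auc.tsv'}")
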