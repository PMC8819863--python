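"""Demographic and biomarker comparison between amyloid groups (Table-1 style).

Continuous variables: median (IQR), Welch t test.  Categorical: counts (%),
Pearson chi-square (uncorrected here; the Yates-corrected variant is a flag).
"""

from pathlib import Path

from plasmapet import compare_groups
from plasmapet.io import read_cohort

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    cohort = read_cohort(OUT / "cohort.csv")
    table = compare_groups(cohort, continuity_correction=False)
    table.to_csv(OUT / "table1.tsv", sep="\t")
    print(table.to_string(float_format=lambda v: f"{v:.3g}"))
    print(f"\nwrote {OUT / 'table1.tsv'}")
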