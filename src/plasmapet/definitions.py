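"""Biomarker registry and cohort schema shared by every stage of the pipeline.

The four plasma biomarkers carry the single-letter codes used throughout the
model-selection analyses: Aβ42/40 = "A", GFAP = "G", NfL = "N",
p-tau181 = "P".  The Aβ42/40 ratio is measured by two assays
(immunoprecipitation mass spectrometry and the Simoa Neuro 4-plex E
immunoassay); which one stands behind code "A" is an analysis-level choice,
so both live in the registry under distinct column names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Direction = Literal["higher", "lower"]

#: Canonical cohort CSV columns, in write order.
COHORT_COLUMNS = [
    "participant_id",
    "diagnosis",        # CU / CI
    "abeta_status",     # negative / positive (amyloid PET, SUVR threshold)
    "age",
    "sex",              # F / M
    "apoe_carrier",     # 0/1, at least one APOE-e4 allele
    "education",
    "mmse",
    "suvr",
    "abeta42_40_ipms",
    "abeta42_40_simoa",
    "gfap",
    "ptau181",
    "nfl",
]

#: Columns holding assay measurements (the only ones perturbation may touch).
BIOMARKER_COLUMNS = [
    "abeta42_40_ipms",
    "abeta42_40_simoa",
    "gfap",
    "ptau181",
    "nfl",
]


@dataclass(frozen=True)
class BiomarkerDef:
    """A plasma biomarker assay: identity, abnormality direction, analytics.

    Parameters
    ----------
    name
        Cohort column name.
    code
        Single-letter model code (``A``/``G``/``P``/``N``).
    direction
        ``"higher"`` if larger values indicate amyloid pathology,
        ``"lower"`` for the Aβ42/40 ratio, which falls with pathology.
    reported_cv
        The assay's reported analytical coefficient of variation
        (fraction, e.g. ``0.04`` for 4%).
    log_transform
        Whether the default model preprocessing log-transforms the column.
    """

    name: str
    code: str
    direction: Direction
    reported_cv: float
    log_transform: bool


#: Assay registry.  Reported CVs: IP-MS Aβ42/40 4.0%, p-tau181 6.6%,
#: NfL 1.2%, Simoa Aβ42/40 1.0%, GFAP 10.5%.  Right-skewed concentration
#: markers are log-transformed before model fitting; the Aβ ratios (small
#: fold change, near-symmetric) enter linearly.
BIOMARKERS: dict[str, BiomarkerDef] = {
    "abeta42_40_ipms": BiomarkerDef("abeta42_40_ipms", "A", "lower", 0.040, False),
    "abeta42_40_simoa": BiomarkerDef("abeta42_40_simoa", "A", "lower", 0.010, False),
    "gfap": BiomarkerDef("gfap", "G", "higher", 0.105, True),
    "ptau181": BiomarkerDef("ptau181", "P", "higher", 0.066, True),
    "nfl": BiomarkerDef("nfl", "N", "higher", 0.012, True),
}

#: Reported per-assay CVs keyed by column, for the "reported-CV" robustness level.
REPORTED_CV_MAP: dict[str, float] = {
    name: d.reported_cv for name, d in BIOMARKERS.items()
}


def abeta_column(assay: str) -> str:
    """Map an Aβ42/40 assay label (``"IP-MS"`` or ``"Simoa"``) to its column."""
    key = assay.replace("-", "").replace("_", "").lower()
    if key == "ipms":
        return "abeta42_40_ipms"
    if key == "simoa":
        return "abeta42_40_simoa"
    raise ValueError(f"unknown Abeta42/40 assay: {assay!r} (expected IP-MS or Simoa)")


def code_columns(codes: str | tuple[str, ...], abeta_assay: str = "IP-MS") -> list[str]:
    """Resolve model codes (subset of ``AGNP``) to cohort columns."""
    out = []
    for c in codes:
        if c == "A":
            out.append(abeta_column(abeta_assay))
        elif c == "G":
            out.append("gfap")
        elif c == "P":
            out.append("ptau181")
        elif c == "N":
            out.append("nfl")
        else:
            raise ValueError(f"unknown biomarker code {c!r}")
    return out
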