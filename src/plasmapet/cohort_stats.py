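"""Group comparison of demographics and biomarkers between amyloid groups.

Continuous variables are summarized as median (IQR) and compared with a
two-sample t test (Welch by default; Student and Mann-Whitney variants
available); categorical variables are summarized as counts (%) and compared
with Pearson's chi-square, with Yates continuity correction configurable
per 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Default Table-1 style variable list: (column, kind).
DEFAULT_VARIABLES: list[tuple[str, str]] = [
    ("age", "continuous"),
    ("diagnosis", "categorical"),
    ("sex", "categorical"),
    ("education", "continuous"),
    ("apoe_carrier", "categorical"),
    ("mmse", "continuous"),
    ("suvr", "continuous"),
    ("abeta42_40_ipms", "continuous"),
    ("abeta42_40_simoa", "continuous"),
    ("gfap", "continuous"),
    ("ptau181", "continuous"),
    ("nfl", "continuous"),
]


@dataclass(frozen=True)
class ComparisonRow:
    variable: str
    summary_negative: str
    summary_positive: str
    test: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def chi2_2x2_uncorrected(table: np.ndarray) -> float:
    """Closed-form uncorrected Pearson chi-square for a 2x2 table:
    ``N (ad - bc)^2 / (r1 r2 c1 c2)``."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("chi-square undefined: empty margin")
    return float(n * (a * d - b * c) ** 2 / denom)


def _median_iqr(x: np.ndarray) -> str:
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return f"{med:.3g} ({q25:.3g}, {q75:.3g})"


def _count_pct(x: pd.Series, level) -> str:
    k = int((x == level).sum())
    return f"{k} ({100.0 * k / len(x):.1f}%)"


def _categorical_levels(x: pd.Series) -> tuple:
    levels = sorted(x.unique())
    # report the "marked" level first where there is a natural one
    for preferred in ("F", "CU", 1):
        if preferred in levels:
            return (preferred,) + tuple(l for l in levels if l != preferred)
    return tuple(levels)


def compare_groups(
    cohort: pd.DataFrame,
    variables: list[tuple[str, str]] | None = None,
    group_column: str = "abeta_status",
    welch: bool = True,
    continuity_correction: bool = False,
    use_mannwhitney: bool = False,
) -> pd.DataFrame:
    """Build a Table-1 style comparison between the two amyloid groups.

    The continuity correction default is off: the study's own printed 2x2
    p-values are internally consistent only if correction usage varied
    between rows, so it is a per-call choice here rather than a fixed
    convention.
    """
    groups = sorted(cohort[group_column].unique())
    if len(groups) != 2:
        raise ValueError(f"grouping column must be binary, found {groups}")
    neg, pos = ("negative", "positive") if set(groups) == {"negative", "positive"} else groups
    g_neg = cohort[cohort[group_column] == neg]
    g_pos = cohort[cohort[group_column] == pos]

    rows = []
    for var, kind in variables or DEFAULT_VARIABLES:
        if kind == "continuous":
            x, y = g_neg[var].to_numpy(float), g_pos[var].to_numpy(float)
            if np.var(x) == 0.0 and np.var(y) == 0.0:
                raise ValueError(f"zero-variance continuous variable {var!r}")
            if use_mannwhitney:
                stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
                test = "Mann-Whitney U"
            else:
                stat, p = stats.ttest_ind(x, y, equal_var=not welch)
                test = "Welch t" if welch else "Student t"
            rows.append(ComparisonRow(var, _median_iqr(x), _median_iqr(y),
                                      test, float(stat), float(p)))
        elif kind == "categorical":
            levels = _categorical_levels(cohort[var])
            table = np.array([
                [(g[var] == l).sum() for l in levels] for g in (g_neg, g_pos)
            ])
            if table.shape[1] < 2:
                raise ValueError(f"categorical variable {var!r} has one level")
            correct = continuity_correction and table.shape == (2, 2)
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                raise ValueError(f"empty margin in contingency table for {var!r}")
            chi2, p, _, _ = stats.chi2_contingency(table, correction=correct)
            test = "Pearson chi2" + (" (Yates)" if correct else "")
            rows.append(ComparisonRow(
                var, _count_pct(g_neg[var], levels[0]),
                _count_pct(g_pos[var], levels[0]), test, float(chi2), float(p)))
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {var!r}")

    return pd.DataFrame([r.__dict__ for r in rows]).set_index("variable")
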