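"""Synthetic cohort generator parameterized by printed summary statistics.

The study sample this generator emulates is a cross-sectional cohort of 118
participants (58 amyloid-PET negative, 60 positive; SUVR threshold 1.11)
with a full plasma-biomarker profile: Aβ42/40 by two assays, GFAP, p-tau181
and NfL, plus age, sex, APOE-ε4 carriership, education, MMSE and the PET
SUVR itself.  Only group-level medians and interquartile ranges of the
marker distributions are published, so each marker is modelled as a
log-normal fitted to those quartiles exactly (two parameters, two printed
quantities beyond the median — the minimal right-skewed positive family that
the summaries identify).  Markers are coupled within each amyloid group
through a Gaussian copula whose correlation matrix is a documented,
configurable assumption.

Because the marginals are known in closed form, the population AUC of every
marker is available analytically (`implied_auc`), which gives downstream
robustness analyses an exact oracle to converge to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import norm

from .definitions import BIOMARKER_COLUMNS, BIOMARKERS, COHORT_COLUMNS, Direction

#: Standard normal upper quartile, z such that Phi(z) = 0.75.
Z75 = float(norm.ppf(0.75))


@dataclass(frozen=True)
class GroupDistribution:
    """Median and quartiles of a positive-valued marker in one amyloid group."""

    median: float
    q25: float
    q75: float

    def __post_init__(self) -> None:
        if not (self.q25 > 0 and self.median > 0 and self.q75 > 0):
            raise ValueError(f"quartiles must be strictly positive: {self}")
        if not (self.q25 < self.median < self.q75):
            raise ValueError(f"require q25 < median < q75: {self}")


def lognormal_params_from_quartiles(d: GroupDistribution) -> tuple[float, float]:
    """Quartile-matching log-normal fit.

    For ``X ~ LogNormal(mu, sigma)`` the median is ``exp(mu)`` and the
    quartiles are ``exp(mu -/+ sigma*z75)``, so

        mu = ln(median),   sigma = ln(q75/q25) / (2*z75),

    reproduces the printed median and IQR endpoints exactly (the fit uses
    the quartile ratio, so an asymmetric printed IQR is matched in ratio,
    not in each endpoint).
    """
    mu = float(np.log(d.median))
    sigma = float(np.log(d.q75 / d.q25) / (2.0 * Z75))
    return mu, sigma


def implied_auc(
    neg: GroupDistribution, pos: GroupDistribution, direction: Direction
) -> float:
    """Exact population AUC between two quartile-matched log-normals.

    With ``ln X`` normal in both groups, the Mann-Whitney probability
    ``P(X_pos > X_neg)`` is ``Phi((mu_pos - mu_neg)/sqrt(s_neg^2 + s_pos^2))``;
    orientation follows the marker's abnormality direction so the returned
    value is the AUC for detecting the positive group.
    """
    mu_n, s_n = lognormal_params_from_quartiles(neg)
    mu_p, s_p = lognormal_params_from_quartiles(pos)
    delta = mu_p - mu_n
    if direction == "lower":
        delta = -delta
    elif direction != "higher":
        raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")
    spread = float(np.hypot(s_n, s_p))
    if spread == 0.0:
        return 0.5 if delta == 0.0 else (1.0 if delta > 0 else 0.0)
    return float(norm.cdf(delta / spread))


# --- printed per-group summaries (median, q25, q75) ------------------------

#: Biomarker medians/IQRs by amyloid group.
DEFAULT_BIOMARKER_DISTRIBUTIONS: dict[str, dict[str, GroupDistribution]] = {
    "abeta42_40_ipms": {
        "negative": GroupDistribution(0.132, 0.128, 0.141),
        "positive": GroupDistribution(0.122, 0.117, 0.127),
    },
    "abeta42_40_simoa": {
        "negative": GroupDistribution(0.050, 0.043, 0.054),
        "positive": GroupDistribution(0.044, 0.040, 0.048),
    },
    "gfap": {
        "negative": GroupDistribution(113.0, 80.7, 154.0),
        "positive": GroupDistribution(164.0, 125.0, 223.0),
    },
    "ptau181": {
        "negative": GroupDistribution(11.7, 8.2, 17.2),
        "positive": GroupDistribution(18.8, 13.1, 23.0),
    },
    "nfl": {
        "negative": GroupDistribution(23.6, 17.7, 36.1),
        "positive": GroupDistribution(31.5, 24.8, 40.1),
    },
}

DEFAULT_SUVR_DISTRIBUTIONS: dict[str, GroupDistribution] = {
    "negative": GroupDistribution(1.00, 0.954, 1.03),
    "positive": GroupDistribution(1.33, 1.22, 1.46),
}

#: Demographics modelled as normals from median/IQR (median as mean,
#: IQR/(2*z75) as SD).  MMSE is truncated to [0, 30] and rounded.
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, tuple[float, float, float]]] = {
    "age": {"negative": (70.8, 66.5, 75.7), "positive": (73.8, 69.9, 77.4)},
    "education": {"negative": (18.0, 14.2, 18.0), "positive": (16.0, 14.0, 18.0)},
    "mmse": {"negative": (29.0, 28.0, 30.0), "positive": (27.5, 24.0, 29.2)},
}


def default_copula_correlation() -> pd.DataFrame:
    """Assumed normal-scores correlation between the five assay columns.

    Not published for this cohort; defaults encode moderate positive
    coupling among the neurodegeneration/astrocyte markers (GFAP, p-tau181,
    NfL: +0.4 pairwise), a mild negative coupling between those and the
    Aβ42/40 ratios (−0.25), and strong agreement between the two Aβ42/40
    assays (+0.6).  Fully overridable through :class:`GeneratorConfig`.
    """
    cols = BIOMARKER_COLUMNS
    m = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    abeta = ["abeta42_40_ipms", "abeta42_40_simoa"]
    neuro = ["gfap", "ptau181", "nfl"]
    m.loc["abeta42_40_ipms", "abeta42_40_simoa"] = 0.6
    for a in neuro:
        for b in neuro:
            if a != b:
                m.loc[a, b] = 0.4
        for c in abeta:
            m.loc[a, c] = m.loc[c, a] = -0.25
    m.loc["abeta42_40_simoa", "abeta42_40_ipms"] = 0.6
    return m


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator parameters; defaults reproduce the study sample.

    ``exact_counts`` draws sex, APOE carriership and the CU/CI split as
    fixed counts (rate rounded times group size) rather than Bernoulli, so
    the printed contingency tables are reproduced exactly.
    """

    n_negative: int = 58
    n_positive: int = 60
    cu_ci_split_by_group: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"negative": (30, 28), "positive": (20, 40)}
    )
    apoe_rate_by_group: dict[str, float] = field(
        default_factory=lambda: {"negative": 0.259, "positive": 0.533}
    )
    female_rate_by_group: dict[str, float] = field(
        default_factory=lambda: {"negative": 0.414, "positive": 0.433}
    )
    biomarker_distributions: dict[str, dict[str, GroupDistribution]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_BIOMARKER_DISTRIBUTIONS.items()
        }
    )
    suvr_distributions: dict[str, GroupDistribution] = field(
        default_factory=lambda: dict(DEFAULT_SUVR_DISTRIBUTIONS)
    )
    suvr_threshold: float = 1.11
    copula_correlation: pd.DataFrame = field(
        default_factory=default_copula_correlation
    )
    exact_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negative <= 0 or self.n_positive <= 0:
            raise ValueError("group sizes must be positive")
        if self.suvr_threshold <= 0:
            raise ValueError("suvr_threshold must be positive")
        for grp, n in (("negative", self.n_negative), ("positive", self.n_positive)):
            cu, ci = self.cu_ci_split_by_group[grp]
            if cu < 0 or ci < 0 or cu + ci != n:
                raise ValueError(
                    f"CU/CI split {cu}/{ci} inconsistent with group size {n} ({grp})"
                )
            for rates in (self.apoe_rate_by_group, self.female_rate_by_group):
                r = rates[grp]
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"rate {r} outside [0, 1]")
        self._copula_cholesky()  # validates symmetry / positive-definiteness

    def with_sizes(self, n_negative: int, n_positive: int) -> "GeneratorConfig":
        """Scaled copy: group sizes replaced, CU/CI splits re-proportioned."""
        splits = {}
        for grp, n in (("negative", n_negative), ("positive", n_positive)):
            cu, ci = self.cu_ci_split_by_group[grp]
            cu_new = int(round(n * cu / (cu + ci)))
            splits[grp] = (cu_new, n - cu_new)
        return replace(
            self,
            n_negative=n_negative,
            n_positive=n_positive,
            cu_ci_split_by_group=splits,
        )

    def _copula_cholesky(self) -> np.ndarray:
        m = self.copula_correlation.loc[BIOMARKER_COLUMNS, BIOMARKER_COLUMNS].to_numpy(
            dtype=float
        )
        if not np.allclose(m, m.T):
            raise ValueError("copula correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("copula correlation matrix must have unit diagonal")
        try:
            return np.linalg.cholesky(m)
        except np.linalg.LinAlgError as exc:
            raise ValueError("copula correlation matrix is not positive-definite") from exc


def _normal_from_quartiles(median: float, q25: float, q75: float) -> tuple[float, float]:
    return median, (q75 - q25) / (2.0 * Z75)


def _exact_count_indicator(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    k = int(round(rate * n))
    vec = np.zeros(n, dtype=int)
    vec[:k] = 1
    return rng.permutation(vec)


def _truncated_lognormal_suvr(
    rng: np.random.Generator,
    n: int,
    dist: GroupDistribution,
    threshold: float,
    side: Literal["below", "above"],
) -> np.ndarray:
    """Sample SUVR from the group log-normal, truncated to one side of the
    positivity threshold so group membership is consistent by construction."""
    mu, sigma = lognormal_params_from_quartiles(dist)
    p_thr = float(norm.cdf((np.log(threshold) - mu) / sigma))
    u = rng.uniform(size=n)
    if side == "below":
        p = u * p_thr
    else:
        p = p_thr + u * (1.0 - p_thr)
    # keep the quantile strictly inside (0, 1)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return np.exp(mu + sigma * norm.ppf(p))


def generate_cohort(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort as a participant-level DataFrame.

    Group sizes, CU/CI splits and (with ``exact_counts``) sex/APOE counts
    are exact; biomarkers are drawn from the group log-normals coupled by
    the Gaussian copula; SUVR is drawn truncated to the correct side of the
    positivity threshold.  The same config (including seed) always yields
    an identical table.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    chol = cfg._copula_cholesky()

    frames = []
    for grp, n, status in (
        ("negative", cfg.n_negative, "negative"),
        ("positive", cfg.n_positive, "positive"),
    ):
        z = rng.standard_normal(size=(n, len(BIOMARKER_COLUMNS))) @ chol.T
        data: dict[str, np.ndarray] = {}
        for j, col in enumerate(BIOMARKER_COLUMNS):
            mu, sigma = lognormal_params_from_quartiles(
                cfg.biomarker_distributions[col][grp]
            )
            data[col] = np.exp(mu + sigma * z[:, j])

        med, q25, q75 = DEFAULT_DEMOGRAPHICS["age"][grp]
        m, s = _normal_from_quartiles(med, q25, q75)
        data["age"] = np.round(m + s * rng.standard_normal(n), 1)
        med, q25, q75 = DEFAULT_DEMOGRAPHICS["education"][grp]
        m, s = _normal_from_quartiles(med, q25, q75)
        data["education"] = np.clip(np.round(m + s * rng.standard_normal(n)), 6, 20)
        med, q25, q75 = DEFAULT_DEMOGRAPHICS["mmse"][grp]
        m, s = _normal_from_quartiles(med, q25, q75)
        data["mmse"] = np.clip(np.round(m + s * rng.standard_normal(n)), 0, 30).astype(int)

        data["suvr"] = _truncated_lognormal_suvr(
            rng, n, cfg.suvr_distributions[grp], cfg.suvr_threshold,
            "below" if grp == "negative" else "above",
        )

        if cfg.exact_counts:
            female = _exact_count_indicator(rng, n, cfg.female_rate_by_group[grp])
            apoe = _exact_count_indicator(rng, n, cfg.apoe_rate_by_group[grp])
        else:
            female = (rng.uniform(size=n) < cfg.female_rate_by_group[grp]).astype(int)
            apoe = (rng.uniform(size=n) < cfg.apoe_rate_by_group[grp]).astype(int)
        cu, ci = cfg.cu_ci_split_by_group[grp]
        diagnosis = rng.permutation(np.array(["CU"] * cu + ["CI"] * ci))

        frame = pd.DataFrame(data)
        frame["diagnosis"] = diagnosis
        frame["abeta_status"] = status
        frame["sex"] = np.where(female == 1, "F", "M")
        frame["apoe_carrier"] = apoe
        frames.append(frame)

    cohort = pd.concat(frames, ignore_index=True)
    cohort["participant_id"] = [f"SYN-{i:05d}" for i in range(1, len(cohort) + 1)]
    cohort = cohort[COHORT_COLUMNS]
    validate_cohort(cohort)
    return cohort


def validate_cohort(cohort: pd.DataFrame, suvr_threshold: float = 1.11) -> None:
    """Raise ``ValueError`` if a cohort table violates its invariants."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {missing}")
    if cohort[COHORT_COLUMNS].isna().any().any():
        bad = cohort.columns[cohort.isna().any()].tolist()
        raise ValueError(f"cohort contains missing values in {bad}")
    for col in BIOMARKER_COLUMNS:
        if (cohort[col] <= 0).any():
            raise ValueError(f"non-positive values in biomarker column {col!r}")
    status_from_suvr = np.where(
        cohort["suvr"] > suvr_threshold, "positive", "negative"
    )
    if not (cohort["abeta_status"].to_numpy() == status_from_suvr).all():
        raise ValueError("abeta_status inconsistent with SUVR vs threshold")
    if not cohort["diagnosis"].isin(["CU", "CI"]).all():
        raise ValueError("diagnosis must be CU or CI")


def abeta_binary(cohort: pd.DataFrame) -> np.ndarray:
    """0/1 amyloid-positivity outcome vector."""
    return (cohort["abeta_status"].to_numpy() == "positive").astype(int)


def biomarker_direction(column: str) -> Direction:
    return BIOMARKERS[column].direction
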