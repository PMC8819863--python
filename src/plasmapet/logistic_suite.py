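"""Logistic models of amyloid-PET positivity over biomarker subsets.

Every model contains a demographic base (age, sex, APOE-ε4 carriership,
plus a CU/CI indicator when fitting all participants together) and one of
the 2^4 subsets of the biomarker codes A/G/N/P.  The suite fits each model
by maximum likelihood, records the information criteria (AIC = 2k − 2logL,
BIC = k·ln n − 2logL, k counting the intercept), four pseudo-R² variants,
and the in-sample AUC of the fitted probabilities, and provides the
likelihood-ratio test between nested fits that the model-selection decision
tree consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2 as chi2_dist

from .definitions import BIOMARKERS, code_columns
from .roc_delong import RocResult, auc_ci
from .synthetic_cohort import abeta_binary

Population = Literal["all", "CU", "CI"]

#: Canonical order of the biomarker codes in model names ("AGNP").
CODE_ORDER = "AGNP"

#: Columns whose skewed distributions get a log transform before centering.
DEFAULT_TRANSFORM_RULES: dict[str, str] = {
    "age": "linear",
    "abeta42_40_ipms": "linear",
    "abeta42_40_simoa": "linear",
    "gfap": "log",
    "ptau181": "log",
    "nfl": "log",
}

#: Maximum |coefficient| on the standardized design before a fit is flagged
#: as quasi-separated.
_SEPARATION_COEF_BOUND = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: biomarker subset + covariate base + population."""

    biomarkers: tuple[str, ...]  # subset of "AGNP", canonically sorted
    covariates: tuple[str, ...] = ("age", "sex_female", "apoe_carrier")
    population: Population = "all"
    abeta_assay: str = "IP-MS"

    def __post_init__(self) -> None:
        codes = tuple(sorted(set(self.biomarkers), key=CODE_ORDER.index))
        if len(codes) != len(self.biomarkers):
            raise ValueError(f"duplicate biomarker codes in {self.biomarkers}")
        object.__setattr__(self, "biomarkers", codes)
        if "diagnosis_ci" in self.covariates and self.population != "all":
            raise ValueError("CU/CI covariate only valid when population='all'")

    @property
    def name(self) -> str:
        """Canonical model name, e.g. ``"AGP"``; ``""`` is demographic-only."""
        return "".join(self.biomarkers)

    def design_columns(self) -> list[str]:
        return list(self.covariates) + code_columns(self.biomarkers, self.abeta_assay)


@dataclass(frozen=True)
class FittedModel:
    """A maximum-likelihood logistic fit plus its selection-relevant summaries."""

    spec: ModelSpec
    loglik: float
    k: int
    n: int
    aic: float
    bic: float
    loglik_null: float
    pseudo_r2: dict[str, float]
    roc: RocResult
    converged: bool
    separation_flag: bool
    params: pd.Series = field(repr=False, compare=False, default=None)
    columns: tuple[str, ...] = ()
    fitted_probabilities: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def usable(self) -> bool:
        """Eligible for model selection: converged and not quasi-separated."""
        return self.converged and not self.separation_flag


def default_covariates(population: Population) -> tuple[str, ...]:
    base = ("age", "sex_female", "apoe_carrier")
    if population == "all":
        base = base + ("diagnosis_ci",)
    return base


def preprocess_predictors(
    cohort: pd.DataFrame, rules: dict[str, str] | None = None
) -> pd.DataFrame:
    """Build the centred design table from a cohort.

    Continuous predictors are log-transformed according to ``rules``
    (``"log"`` or ``"linear"``) and then mean-centred; binary predictors are
    coded 0/1 (``sex_female``, ``apoe_carrier``, ``diagnosis_ci``).
    Centering does not change likelihoods, information criteria or fitted
    probabilities — it only conditions the optimisation.  The transform
    actually applied to each column is recorded in
    ``design.attrs["transforms"]``.
    """
    rules = {**DEFAULT_TRANSFORM_RULES, **(rules or {})}
    design = pd.DataFrame(index=cohort.index)
    applied: dict[str, str] = {}
    for col, rule in rules.items():
        if col not in cohort.columns:
            continue
        x = cohort[col].to_numpy(dtype=float)
        if rule == "log":
            if (x <= 0).any():
                raise ValueError(
                    f"log transform requested for {col!r} but it has non-positive values"
                )
            x = np.log(x)
        elif rule != "linear":
            raise ValueError(f"unknown transform rule {rule!r} for {col!r}")
        design[col] = x - x.mean()
        applied[col] = rule
    design["sex_female"] = (cohort["sex"].to_numpy() == "F").astype(float)
    design["apoe_carrier"] = cohort["apoe_carrier"].to_numpy(dtype=float)
    design["diagnosis_ci"] = (cohort["diagnosis"].to_numpy() == "CI").astype(float)
    design.attrs["transforms"] = applied
    return design


def intercept_only_loglik(outcome: np.ndarray) -> float:
    """Closed-form log-likelihood of the intercept-only logistic model."""
    y = np.asarray(outcome)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("outcome must contain both classes")
    p = n1 / len(y)
    return float(n1 * np.log(p) + n0 * np.log(1.0 - p))


def fit_logistic(
    design: pd.DataFrame, outcome: np.ndarray, spec: ModelSpec
) -> FittedModel:
    """Fit one candidate model by Newton IRLS and summarize it.

    Non-convergence and quasi-separation (runaway coefficients or a
    complete-separation likelihood) set flags on the result instead of
    raising, so bulk fitting over all subsets never aborts; flagged fits are
    excluded from model selection downstream.
    """
    y = np.asarray(outcome, dtype=float)
    cols = spec.design_columns()
    missing = [c for c in cols if c not in design.columns]
    if missing:
        raise ValueError(f"design table lacks columns {missing}")
    n = len(design)
    X = sm.add_constant(design[cols], has_constant="add")
    k = X.shape[1]
    if n <= k:
        raise ValueError(f"n = {n} too small for k = {k} parameters")
    if y.sum() in (0, len(y)):
        raise ValueError("outcome must contain both classes")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        corr = np.corrcoef(design[cols].to_numpy(), rowvar=False)
        aliased = [
            f"{cols[i]}~{cols[j]}"
            for i in range(len(cols))
            for j in range(i + 1, len(cols))
            if abs(corr[i, j]) > 1.0 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased or cols}")

    converged = True
    separation = False
    try:
        res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100, tol=1e-8)
        converged = bool(res.mle_retvals.get("converged", True))
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        # complete separation: Newton diverges; take a bounded quasi-fit and flag
        res = sm.Logit(y, X).fit(disp=0, method="lbfgs", maxiter=200)
        converged = False
        separation = True

    params = pd.Series(res.params, index=X.columns)
    scale = design[cols].std(ddof=0).replace(0.0, 1.0) if cols else pd.Series(dtype=float)
    if cols and (params[cols].abs() * scale).max() > _SEPARATION_COEF_BOUND:
        separation = True
    llf = float(res.llf)
    if llf > -1e-6 * n:  # essentially perfect in-sample fit
        separation = True

    probs = np.asarray(res.predict(X))
    ll0 = intercept_only_loglik(y)
    aic = 2.0 * k - 2.0 * llf
    bic = k * np.log(n) - 2.0 * llf
    r2 = pseudo_r2_map(llf, ll0, n=n, k=k)
    roc = auc_ci(probs, y.astype(int), direction="higher")
    return FittedModel(
        spec=spec,
        loglik=llf,
        k=k,
        n=n,
        aic=float(aic),
        bic=float(bic),
        loglik_null=ll0,
        pseudo_r2=r2,
        roc=roc,
        converged=converged,
        separation_flag=separation,
        params=params,
        columns=tuple(X.columns),
        fitted_probabilities=probs,
    )


def pseudo_r2_map(loglik: float, loglik_null: float, n: int, k: int) -> dict[str, float]:
    """The four standard logistic pseudo-R² variants.

    McFadden ``1 − logL/logL0``; Cox–Snell ``1 − exp(2(logL0 − logL)/n)``;
    Nagelkerke rescales Cox–Snell to a [0, 1] maximum; adjusted McFadden
    penalizes by the parameter count, ``1 − (logL − k)/logL0``.
    """
    if loglik_null == 0.0:
        raise ValueError("degenerate null likelihood")
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik) / n)
    return {
        "mcfadden": 1.0 - loglik / loglik_null,
        "cox_snell": float(cox_snell),
        "nagelkerke": float(cox_snell / (1.0 - np.exp(2.0 * loglik_null / n))),
        "mcfadden_adjusted": 1.0 - (loglik - k) / loglik_null,
    }


def bic_from_aic(aic: float, k: int, n: int) -> float:
    """BIC implied by an AIC: ``BIC = AIC + k (ln n − 2)``.

    Both criteria share −2logL, so the identity holds for every fit and
    lets a published AIC/BIC pair be checked for consistency (and its
    parameter count recovered).
    """
    return aic + k * (np.log(n) - 2.0)


def lrt_chi2_vs_null_from_aic(aic: float, k: int, n_pos: int, n_neg: int) -> float:
    """LRT statistic vs the intercept-only null, from an AIC alone.

    ``logL = (2k − AIC)/2`` and the null log-likelihood of an
    ``n_pos``/``n_neg`` split is closed-form, so the chi-square
    ``2(logL − logL0)`` is fully determined by (AIC, k) and the class
    counts.
    """
    loglik = (2.0 * k - aic) / 2.0
    y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
    return 2.0 * (loglik - intercept_only_loglik(y))


def likelihood_ratio_test(
    small: FittedModel, large: FittedModel
) -> tuple[float, int, float]:
    """LRT between nested fits on the same rows: ``(chi2, df, p)``."""
    if small.n != large.n:
        raise ValueError("LRT requires fits on the same rows (n differs)")
    if not set(small.columns) <= set(large.columns):
        raise ValueError(
            f"models not nested: {small.spec.name or 'demographic'} is not a "
            f"subset of {large.spec.name or 'demographic'}"
        )
    df = large.k - small.k
    chi2 = 2.0 * (large.loglik - small.loglik)
    if chi2 < -1e-6:
        raise ValueError(f"nested log-likelihood decreased by {-chi2:.2e}")
    chi2 = max(chi2, 0.0)
    p = float(chi2_dist.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), df, p


def enumerate_models(
    codes: str = "AGNP",
    population: Population = "all",
    abeta_assay: str = "IP-MS",
    covariates: tuple[str, ...] | None = None,
) -> list[ModelSpec]:
    """All 2^m biomarker subsets (including the demographic-only model),
    canonical names, deterministic order (by size, then name)."""
    codes_sorted = sorted(set(codes), key=CODE_ORDER.index)
    if len(codes_sorted) != len(codes):
        raise ValueError(f"duplicate biomarker codes in {codes!r}")
    cov = covariates if covariates is not None else default_covariates(population)
    specs = []
    for mask in range(2 ** len(codes_sorted)):
        subset = tuple(c for i, c in enumerate(codes_sorted) if mask >> i & 1)
        specs.append(
            ModelSpec(subset, covariates=cov, population=population,
                      abeta_assay=abeta_assay)
        )
    specs.sort(key=lambda s: (len(s.biomarkers), s.name))
    return specs


def filter_population(cohort: pd.DataFrame, population: Population) -> pd.DataFrame:
    if population == "all":
        return cohort
    return cohort[cohort["diagnosis"] == population].reset_index(drop=True)


def fit_model_family(
    cohort: pd.DataFrame,
    population: Population = "all",
    abeta_assay: str = "IP-MS",
    codes: str = "AGNP",
    rules: dict[str, str] | None = None,
) -> dict[str, FittedModel]:
    """Preprocess once and fit every biomarker subset on one population."""
    sub = filter_population(cohort, population)
    design = preprocess_predictors(sub, rules)
    y = abeta_binary(sub)
    fits = {}
    for spec in enumerate_models(codes, population, abeta_assay):
        fits[spec.name] = fit_logistic(design, y, spec)
    return fits


def model_summary_table(
    fits: dict[str, FittedModel], reference: str = "null"
) -> pd.DataFrame:
    """Per-model summary: AIC, BIC, pseudo-R², AUC (95% CI), LRT vs reference.

    ``reference`` is ``"null"`` (intercept-only, closed form) or
    ``"demographic"`` (the empty-subset model); both references are reported
    in the study outputs since the printed tables are ambiguous about which
    was used.
    """
    rows = []
    demographic = fits.get("")
    for name, fm in sorted(fits.items(), key=lambda kv: (len(kv[0]), kv[0])):
        row = {
            "model": name or "(demographic)",
            "aic": fm.aic,
            "bic": fm.bic,
            "r2_mcfadden": fm.pseudo_r2["mcfadden"],
            "r2_mcfadden_adjusted": fm.pseudo_r2["mcfadden_adjusted"],
            "r2_cox_snell": fm.pseudo_r2["cox_snell"],
            "r2_nagelkerke": fm.pseudo_r2["nagelkerke"],
            "auc": fm.roc.auc,
            "auc_ci_low": fm.roc.ci_low,
            "auc_ci_high": fm.roc.ci_high,
            "converged": fm.converged,
            "separation_flag": fm.separation_flag,
        }
        # LRT vs the intercept-only null (closed form)
        chi2_null = 2.0 * (fm.loglik - fm.loglik_null)
        row["lrt_chi2_vs_null"] = chi2_null
        row["lrt_p_vs_null"] = float(chi2_dist.sf(chi2_null, fm.k - 1))
        if reference == "demographic" and demographic is not None and name:
            chi2, df, p = likelihood_ratio_test(demographic, fm)
            row["lrt_chi2_vs_demographic"] = chi2
            row["lrt_p_vs_demographic"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
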