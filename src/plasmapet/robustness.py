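"""Robustness analyses under simulated analytical variability.

Two experiments, mirroring the study design:

1. Single-biomarker AUC-vs-CV curves: each biomarker's discrimination of
   amyloid status is re-estimated after multiplicative noise bounded by a
   CV level, over a grid of levels (default 0–20% in 1% steps), averaged
   over iterations.

2. Model-selection frequency: at each CV level (including a "reported"
   level using each assay's published CV) the full model family is refitted
   on perturbed measurements and the decision tree re-run, tallying how
   often each model is selected across iterations (default 10).

Because the synthetic marginals are log-normal, the *population* effect of
the noise is available in closed form (`noisy_implied_auc`): on the log
scale the noise adds an independent variance of ``Var[ln(1+U)]`` to each
group, so markers whose group separation rests on a small log-scale shift
(the Aβ42/40 ratios, ~8% fold change) degrade sharply while high-fold-change
markers (GFAP, p-tau181) barely move.  That oracle is what the empirical
curves are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.stats import norm

from .definitions import BIOMARKER_COLUMNS, BIOMARKERS, REPORTED_CV_MAP, Direction
from .logistic_suite import Population, fit_model_family, filter_population
from .perturbation import NoiseDistribution, PerturbationConfig, perturb
from .roc_delong import auc
from .selection import select_best_model
from .synthetic_cohort import (
    GroupDistribution,
    abeta_binary,
    lognormal_params_from_quartiles,
)

#: The single-biomarker robustness grid: 0% plus 1%..20% in 1% steps.
DEFAULT_CV_GRID: tuple[float, ...] = tuple(np.round(np.arange(0, 21) / 100.0, 2))

#: The model-selection robustness levels: reported per-assay CVs, then
#: common 5/10/15/20% bounds.
DEFAULT_SELECTION_LEVELS: tuple[object, ...] = ("reported", 0.05, 0.10, 0.15, 0.20)


def log_noise_moments(c: float, distribution: NoiseDistribution = "uniform"
                      ) -> tuple[float, float]:
    """Mean and variance of ``ln(1 + U)`` for noise ``U`` on [-c, +c].

    Computed by quadrature against the noise density (uniform, or normal
    with SD c/2 truncated at two SDs).  Both are exact up to quadrature
    tolerance; the variance is what shifts the population AUC.
    """
    if c == 0.0:
        return 0.0, 0.0
    if c >= 1.0:
        raise ValueError("CV bound must be < 1 for finite log-noise moments")
    if distribution == "uniform":
        def dens(u: float) -> float:
            return 1.0 / (2.0 * c)
    elif distribution == "truncated_normal":
        sd = c / 2.0
        z = norm.cdf(2.0) - norm.cdf(-2.0)
        def dens(u: float) -> float:
            return norm.pdf(u, scale=sd) / z
    else:
        raise ValueError(f"unknown noise distribution {distribution!r}")
    mean = quad(lambda u: np.log1p(u) * dens(u), -c, c)[0]
    second = quad(lambda u: np.log1p(u) ** 2 * dens(u), -c, c)[0]
    return mean, second - mean**2


def noisy_implied_auc(
    neg: GroupDistribution,
    pos: GroupDistribution,
    direction: Direction,
    cv: float,
    distribution: NoiseDistribution = "uniform",
) -> float:
    """Population AUC of a quartile-matched log-normal marker under noise.

    Noise multiplies both groups by ``(1+U)``, adding ``Var[ln(1+U)]`` to
    each group's log-scale variance; the log-noise is treated as normal in
    the two-group difference (an excellent approximation for c <= 0.2), so

        AUC = Phi(|d_mu| / sqrt(s_neg^2 + s_pos^2 + 2*Var[ln(1+U)])).

    Non-increasing in ``cv`` by construction.
    """
    mu_n, s_n = lognormal_params_from_quartiles(neg)
    mu_p, s_p = lognormal_params_from_quartiles(pos)
    delta = mu_p - mu_n
    if direction == "lower":
        delta = -delta
    _, var_noise = log_noise_moments(cv, distribution)
    denom = np.sqrt(s_n**2 + s_p**2 + 2.0 * var_noise)
    return float(norm.cdf(delta / denom))


@dataclass(frozen=True)
class AucCurve:
    """Mean and min–max band of a biomarker's AUC across CV levels."""

    biomarker: str
    population: Population
    cv_grid: tuple[float, ...]
    auc_mean: tuple[float, ...]
    auc_low: tuple[float, ...]
    auc_high: tuple[float, ...]
    iterations: int

    def __post_init__(self) -> None:
        lengths = {len(self.cv_grid), len(self.auc_mean),
                   len(self.auc_low), len(self.auc_high)}
        if len(lengths) != 1:
            raise ValueError("cv grid and AUC vectors must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "biomarker": self.biomarker,
            "population": self.population,
            "cv": self.cv_grid,
            "auc_mean": self.auc_mean,
            "auc_low": self.auc_low,
            "auc_high": self.auc_high,
            "iterations": self.iterations,
        })


@dataclass(frozen=True)
class SelectionFrequency:
    """How often each model won the decision tree at one CV level."""

    population: Population
    abeta_assay: str
    cv_level: object  # fraction, or the string "reported"
    counts: dict[str, int]
    iterations: int
    failures: int = 0

    def __post_init__(self) -> None:
        if sum(self.counts.values()) + self.failures != self.iterations:
            raise ValueError("selection counts plus failures must sum to iterations")

    def modal_model(self) -> str:
        return min(self.counts, key=lambda k: (-self.counts[k], k))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"population": self.population, "abeta_assay": self.abeta_assay,
             "cv_level": self.cv_level, "model": m or "(demographic)",
             "count": c, "iterations": self.iterations}
            for m, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)


def _level_seed(seed: int, level_index: int) -> int:
    """Deterministic sub-seed for one CV level (kept below 2^31)."""
    return int(np.random.SeedSequence([seed, level_index]).generate_state(1)[0]
               % (2**31 - 1))


def auc_vs_cv(
    cohort: pd.DataFrame,
    biomarker: str,
    cv_grid: Sequence[float] = DEFAULT_CV_GRID,
    iterations: int = 10,
    seed: int = 0,
    population: Population = "all",
    distribution: NoiseDistribution = "uniform",
) -> AucCurve:
    """Empirical AUC-vs-CV curve for one biomarker.

    The cv = 0 entry is the exact unperturbed AUC; every other level
    averages ``iterations`` independent perturbations, with min–max bands.
    """
    if biomarker not in BIOMARKER_COLUMNS:
        raise ValueError(f"unknown biomarker column {biomarker!r}")
    sub = filter_population(cohort, population)
    labels = abeta_binary(sub)
    if labels.sum() in (0, len(labels)):
        raise ValueError("population stratum has a single amyloid class")
    direction = BIOMARKERS[biomarker].direction

    means, lows, highs = [], [], []
    for li, cv in enumerate(cv_grid):
        if cv == 0.0:
            a0 = auc(sub[biomarker].to_numpy(), labels, direction)
            means.append(a0); lows.append(a0); highs.append(a0)
            continue
        cfg = PerturbationConfig(cv_map={biomarker: float(cv)},
                                 distribution=distribution,
                                 iterations=iterations,
                                 seed=_level_seed(seed, li))
        vals = [
            auc(perturb(sub, cfg, i)[biomarker].to_numpy(), labels, direction)
            for i in range(iterations)
        ]
        means.append(float(np.mean(vals)))
        lows.append(float(np.min(vals)))
        highs.append(float(np.max(vals)))
    return AucCurve(
        biomarker=biomarker,
        population=population,
        cv_grid=tuple(float(c) for c in cv_grid),
        auc_mean=tuple(means),
        auc_low=tuple(lows),
        auc_high=tuple(highs),
        iterations=iterations,
    )


def _cv_map_for_level(level, abeta_assay: str) -> dict[str, float]:
    if level == "reported":
        return dict(REPORTED_CV_MAP)
    c = float(level)
    return {col: c for col in BIOMARKER_COLUMNS}


def selection_robustness(
    cohort: pd.DataFrame,
    population: Population = "all",
    abeta_assay: str = "IP-MS",
    cv_levels: Sequence[object] = DEFAULT_SELECTION_LEVELS,
    iterations: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    aic_window: float = 2.0,
    distribution: NoiseDistribution = "uniform",
    codes: str = "AGNP",
) -> list[SelectionFrequency]:
    """Model-selection frequency tables across CV levels.

    For each level and iteration: perturb the biomarker columns, refit the
    whole model family on the requested population, run the decision tree
    and tally the selected model.  Iterations that fail (no usable fit)
    are recorded as failures rather than aborting the level.
    """
    results = []
    for li, level in enumerate(cv_levels):
        cv_map = _cv_map_for_level(level, abeta_assay)
        cfg = PerturbationConfig(cv_map=cv_map, distribution=distribution,
                                 iterations=iterations,
                                 seed=_level_seed(seed, li))
        counts: dict[str, int] = {}
        failures = 0
        for i in range(iterations):
            noisy = perturb(cohort, cfg, i)
            try:
                fits = fit_model_family(noisy, population, abeta_assay, codes)
                sel = select_best_model(fits, alpha=alpha, aic_window=aic_window)
            except ValueError:
                failures += 1
                continue
            counts[sel.selected.name] = counts.get(sel.selected.name, 0) + 1
        results.append(SelectionFrequency(
            population=population, abeta_assay=abeta_assay, cv_level=level,
            counts=counts, iterations=iterations, failures=failures,
        ))
    return results


def frequency_table(frequencies: list[SelectionFrequency]) -> pd.DataFrame:
    """Long-format table over all CV levels (one row per model per level)."""
    return pd.concat([f.to_frame() for f in frequencies], ignore_index=True)
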