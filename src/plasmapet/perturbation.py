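"""Simulated analytical variability: bounded multiplicative noise per assay.

Each perturbed measurement is ``x' = x * (1 + u)`` with ``u`` supported on
``[-c, +c]`` where ``c`` is the simulated CV for the assay.  Noise is drawn
either uniformly on the interval (default — the variability is "within and
up to" the stated percentage) or from a normal with SD ``c/2`` truncated at
the bounds.  The Aβ42/40 ratio is treated as a single assay value, never as
separate numerator/denominator perturbations.  Demographics, SUVR and group
labels are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .definitions import BIOMARKER_COLUMNS, REPORTED_CV_MAP

NoiseDistribution = Literal["uniform", "truncated_normal"]


@dataclass(frozen=True)
class PerturbationConfig:
    """Per-assay CV bounds plus the noise law and iteration bookkeeping."""

    cv_map: dict[str, float] = field(default_factory=lambda: dict(REPORTED_CV_MAP))
    distribution: NoiseDistribution = "uniform"
    iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.cv_map) - set(BIOMARKER_COLUMNS)
        if unknown:
            raise ValueError(f"unknown assay columns in cv_map: {sorted(unknown)}")
        for col, c in self.cv_map.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"CV for {col!r} must lie in [0, 1], got {c}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.distribution not in ("uniform", "truncated_normal"):
            raise ValueError(f"unknown noise distribution {self.distribution!r}")


def noise_rng(seed: int, *indices: int) -> np.random.Generator:
    """Deterministic per-iteration stream.

    Seeded from the entropy sequence ``(seed, *indices)`` (e.g. base seed,
    CV-level index, iteration index) so each iteration is reproducible in
    isolation and independent of the others.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, *indices]))


def draw_relative_noise(
    rng: np.random.Generator, n: int, c: float, distribution: NoiseDistribution
) -> np.ndarray:
    """Draw ``u`` on [-c, +c]; uniform, or normal(0, c/2) truncated at +/-c."""
    if c == 0.0:
        return np.zeros(n)
    if distribution == "uniform":
        return rng.uniform(-c, c, size=n)
    # truncated normal: sd = c/2, bounds at two SDs
    return truncnorm.rvs(-2.0, 2.0, loc=0.0, scale=c / 2.0, size=n, random_state=rng)


def perturb(
    cohort: pd.DataFrame, cfg: PerturbationConfig, iteration_index: int = 0
) -> pd.DataFrame:
    """Return a copy of the cohort with noisy biomarker columns.

    Only columns named in ``cfg.cv_map`` change; the draw for iteration
    ``i`` under seed ``s`` comes from the stream ``noise_rng(s, i)`` and is
    therefore reproducible and independent across iterations.  Provenance
    is recorded in ``out.attrs["perturbation"]``.
    """
    missing = [c for c in cfg.cv_map if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks assay columns: {missing}")
    if iteration_index < 0:
        raise ValueError("iteration_index must be >= 0")

    rng = noise_rng(cfg.seed, iteration_index)
    out = cohort.copy()
    n = len(cohort)
    for col in BIOMARKER_COLUMNS:  # fixed order, so streams are stable
        if col not in cfg.cv_map:
            continue
        u = draw_relative_noise(rng, n, cfg.cv_map[col], cfg.distribution)
        out[col] = cohort[col].to_numpy() * (1.0 + u)
    out.attrs["perturbation"] = {
        "cv_map": dict(cfg.cv_map),
        "distribution": cfg.distribution,
        "seed": cfg.seed,
        "iteration": iteration_index,
    }
    return out
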