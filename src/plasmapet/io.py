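"""Cohort I/O, run configuration and end-to-end orchestration.

The pipeline stages mirror the study's analysis order: cohort (generated or
loaded) → group comparison table → single-marker ROC / assay comparison →
single-biomarker robustness curves → model fitting and decision-tree
selection per population and assay → selection-robustness frequency tables.
Every run writes a machine-readable manifest carrying the seed, package
versions and a hash of the configuration, so any output can be reproduced
from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import compare_groups
from .definitions import BIOMARKER_COLUMNS, BIOMARKERS, COHORT_COLUMNS, abeta_column
from .logistic_suite import Population, fit_model_family, model_summary_table
from .robustness import (
    DEFAULT_CV_GRID,
    DEFAULT_SELECTION_LEVELS,
    auc_vs_cv,
    frequency_table,
    selection_robustness,
)
from .roc_delong import roc_report
from .selection import select_best_model
from .synthetic_cohort import (
    GeneratorConfig,
    GroupDistribution,
    abeta_binary,
    generate_cohort,
    validate_cohort,
)

log = logging.getLogger("plasmapet")

#: Columns that must be present and numeric in a loaded cohort.
_NUMERIC_COLUMNS = ["age", "education", "mmse", "suvr"] + BIOMARKER_COLUMNS
_REQUIRED_COLUMNS = COHORT_COLUMNS


def read_cohort(path: str | Path, suvr_threshold: float = 1.11) -> pd.DataFrame:
    """Load and validate a participant-level cohort CSV.

    Rows with missing required fields are dropped with a warning
    (complete-case analysis); missing columns and non-numeric biomarker
    values raise with the offending names / row indices.
    """
    raw = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing required columns: {missing}")
    for col in _NUMERIC_COLUMNS:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {col!r} at row index {int(bad.idxmax())}"
            )
        raw[col] = converted
    n_before = len(raw)
    cohort = raw.dropna(subset=_REQUIRED_COLUMNS).reset_index(drop=True)
    if len(cohort) < n_before:
        warnings.warn(
            f"dropped {n_before - len(cohort)} incomplete rows "
            f"(complete-case analysis); {len(cohort)} remain",
            stacklevel=2,
        )
    log.info("loaded cohort: %d rows, %d positive", len(cohort),
             int(abeta_binary(cohort).sum()))
    validate_cohort(cohort, suvr_threshold)
    return cohort


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, GroupDistribution):
        return {"median": obj.median, "q25": obj.q25, "q75": obj.q75}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_to_dict(config) -> dict:
    return _jsonable(config)


def config_hash(config) -> str:
    payload = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_config(config, path: str | Path) -> None:
    path = Path(path)
    payload = config_to_dict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    Exactly one of ``input_path`` / ``generator`` must be set; the rest
    parameterize the analysis stages.
    """

    input_path: str | None = None
    generator: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    populations: tuple[Population, ...] = ("all", "CU", "CI")
    abeta_assays: tuple[str, ...] = ("IP-MS", "Simoa")
    curve_cv_grid: tuple[float, ...] = DEFAULT_CV_GRID
    curve_iterations: int = 10
    selection_cv_levels: tuple[object, ...] = DEFAULT_SELECTION_LEVELS
    selection_iterations: int = 10
    alpha: float = 0.05
    aic_window: float = 2.0
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("set exactly one of input_path or generator")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle under ``output_dir``.

    Returns a dict of the in-memory results keyed by stage.  All outputs
    are reproducible from (config, seed): the manifest records both.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        cohort = generate_cohort(gen)
        write_cohort(cohort, out / "cohort.csv")
        write_config(gen, out / "generator_config.yaml")
    else:
        cohort = read_cohort(config.input_path)
    results["cohort"] = cohort

    table1 = compare_groups(cohort)
    table1.to_csv(out / "table1.tsv", sep="\t")
    results["table1"] = table1

    labels = abeta_binary(cohort)
    markers = {
        name: (cohort[name].to_numpy(), BIOMARKERS[name].direction)
        for name in BIOMARKER_COLUMNS
    }
    assay_report = roc_report(markers, labels)
    assay_report.to_csv(out / "single_biomarker_auc.tsv", sep="\t")
    results["single_biomarker_auc"] = assay_report

    curves = []
    for pop in config.populations:
        for name in BIOMARKER_COLUMNS:
            curves.append(auc_vs_cv(
                cohort, name, config.curve_cv_grid,
                iterations=config.curve_iterations, seed=config.seed,
                population=pop,
            ).to_frame())
    curve_table = pd.concat(curves, ignore_index=True)
    curve_table.to_csv(out / "auc_vs_cv.tsv", sep="\t", index=False)
    results["auc_vs_cv"] = curve_table

    selections = {}
    for assay in config.abeta_assays:
        for pop in config.populations:
            fits = fit_model_family(cohort, pop, assay)
            summary = model_summary_table(fits, reference="demographic")
            tag = f"{pop}_{assay.replace('-', '').lower()}"
            summary.to_csv(out / f"model_summary_{tag}.tsv", sep="\t")
            sel = select_best_model(fits, config.alpha, config.aic_window)
            (out / f"selection_{tag}.json").write_text(sel.to_json(indent=2))
            selections[(pop, assay)] = sel
            log.info("selected model for %s/%s: %r", pop, assay,
                     sel.selected.name or "(demographic)")
    results["selections"] = selections

    freq_frames = []
    for assay in config.abeta_assays:
        for pop in config.populations:
            freqs = selection_robustness(
                cohort, pop, assay, config.selection_cv_levels,
                iterations=config.selection_iterations, seed=config.seed,
                alpha=config.alpha, aic_window=config.aic_window,
            )
            freq_frames.append(frequency_table(freqs))
    freq_table = pd.concat(freq_frames, ignore_index=True)
    freq_table.to_csv(out / "selection_frequency.tsv", sep="\t", index=False)
    results["selection_frequency"] = freq_table

    manifest = {
        "plasmapet_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config_to_dict(config),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
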