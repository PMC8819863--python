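"""The model-selection decision tree: best AIC → LRT screen → lowest BIC.

Among all candidate fits, the best-fitting model is the one with the lowest
AIC.  Every model within ``aic_window`` (default 2) AIC units of it is a
candidate; each candidate that is nested with the best-AIC model (either
direction) is compared to it by a likelihood-ratio test and excluded when
the test is significant at ``alpha`` *and* favors the best-AIC model —
i.e. the candidate is the inferior (subset) member of the nested pair.
Non-nested candidates cannot be LR-tested and are retained, flagged.  The
selected model is then the one with the lowest BIC among the best-AIC model
and the surviving candidates.  Ties break toward fewer parameters, then the
lexicographically smaller name, so the procedure is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .logistic_suite import FittedModel, ModelSpec, likelihood_ratio_test


@dataclass(frozen=True)
class SelectionResult:
    """Full audit trail of one pass through the decision tree."""

    selected: ModelSpec
    best_aic: ModelSpec
    candidates: list[tuple[ModelSpec, float]]          # (spec, delta AIC)
    excluded_by_lrt: list[tuple[ModelSpec, float, float]]  # (spec, chi2, p)
    kept_non_nested: list[ModelSpec]
    bic_ranking: list[tuple[ModelSpec, float]]
    alpha: float = 0.05
    aic_window: float = 2.0

    def to_dict(self) -> dict:
        return {
            "selected": self.selected.name,
            "best_aic": self.best_aic.name,
            "candidates": [[s.name, d] for s, d in self.candidates],
            "excluded_by_lrt": [[s.name, c, p] for s, c, p in self.excluded_by_lrt],
            "kept_non_nested": [s.name for s in self.kept_non_nested],
            "bic_ranking": [[s.name, b] for s, b in self.bic_ranking],
            "alpha": self.alpha,
            "aic_window": self.aic_window,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _tiebreak_key(fm: FittedModel, criterion: float) -> tuple:
    return (criterion, fm.k, fm.spec.name)


def _nested_pair(a: FittedModel, b: FittedModel) -> tuple[FittedModel, FittedModel] | None:
    """Order (small, large) if one design is a subset of the other, else None."""
    ca, cb = set(a.columns), set(b.columns)
    if ca <= cb:
        return a, b
    if cb <= ca:
        return b, a
    return None


def select_best_model(
    models: list[FittedModel] | dict[str, FittedModel],
    alpha: float = 0.05,
    aic_window: float = 2.0,
) -> SelectionResult:
    """Run the decision tree over a family of fitted models.

    Flagged (non-converged or quasi-separated) fits are ignored; an empty
    usable set, or non-finite criteria, raise ``ValueError``.
    """
    if isinstance(models, dict):
        models = list(models.values())
    usable = [m for m in models if m.usable]
    if not usable:
        raise ValueError("no converged, unflagged model to select from")
    for m in usable:
        if not (np.isfinite(m.aic) and np.isfinite(m.bic)):
            raise ValueError(f"non-finite criteria for model {m.spec.name!r}")
    ns = {m.n for m in usable}
    if len(ns) > 1:
        raise ValueError(f"models fitted on different row counts: {sorted(ns)}")

    best = min(usable, key=lambda m: _tiebreak_key(m, m.aic))
    aic_min = best.aic
    candidates = [
        m for m in usable
        if m is not best and m.aic - aic_min <= aic_window
    ]

    excluded: list[tuple[ModelSpec, float, float]] = []
    kept_non_nested: list[ModelSpec] = []
    survivors: list[FittedModel] = []
    for cand in candidates:
        pair = _nested_pair(cand, best)
        if pair is None:
            kept_non_nested.append(cand.spec)
            survivors.append(cand)
            continue
        small, large = pair
        chi2, df, p = likelihood_ratio_test(small, large)
        # exclusion only when the test is significant AND the candidate is
        # the inferior (subset) member of the pair
        if p < alpha and small is cand:
            excluded.append((cand.spec, chi2, p))
        else:
            survivors.append(cand)

    pool = [best] + survivors
    ranking = sorted(pool, key=lambda m: _tiebreak_key(m, m.bic))
    selected = ranking[0]
    return SelectionResult(
        selected=selected.spec,
        best_aic=best.spec,
        candidates=[(m.spec, m.aic - aic_min) for m in candidates],
        excluded_by_lrt=excluded,
        kept_non_nested=kept_non_nested,
        bic_ranking=[(m.spec, m.bic) for m in ranking],
        alpha=alpha,
        aic_window=aic_window,
    )
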