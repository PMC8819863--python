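"""AUC estimation and DeLong inference for correlated ROC curves.

The AUC is the Mann-Whitney pair statistic: over all (positive, negative)
pairs, the fraction in which the positive participant's score is ranked
more abnormal, counting ties as 1/2.  Its variance, and the covariance
between the AUCs of two markers measured on the *same* participants, come
from DeLong's structural components (per-participant placement values),
computed here with midranks in O(n log n); the O(n_pos * n_neg) pair count
is kept in the test-suite as an oracle.

``direction="higher"`` means larger scores indicate the positive class;
``"lower"`` (e.g. the Aβ42/40 ratio) flips the orientation, mapping AUC to
1 − AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .definitions import Direction


@dataclass(frozen=True)
class RocResult:
    """An AUC with its normal-approximation confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    direction: Direction
    se: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must bracket the AUC estimate")


def _oriented(scores: np.ndarray, direction: Direction) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if direction == "lower":
        return -scores
    if direction != "higher":
        raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")
    return scores


def _split(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: need at least one participant per class")
    if len(pos) + len(neg) != len(labels):
        raise ValueError("labels must be binary 0/1")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement components via midranks.

    Returns ``(auc, v_pos, v_neg)`` where ``v_pos[i]`` is the fraction of
    negatives the i-th positive outranks (ties half-counted) and ``v_neg[j]``
    the fraction of positives the j-th negative is outranked by.  Both have
    mean equal to the AUC.
    """
    m, n = len(pos), len(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    tx = rankdata(pos)
    ty = rankdata(neg)
    v_pos = (tz[:m] - tx) / n
    v_neg = 1.0 - (tz[m:] - ty) / m
    auc = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    return auc, v_pos, v_neg


def auc(scores, labels, direction: Direction = "higher") -> float:
    """Mann-Whitney AUC of ``scores`` for the positive class."""
    pos, neg = _split(_oriented(np.asarray(scores, dtype=float), direction),
                      np.asarray(labels))
    a, _, _ = _placements(pos, neg)
    return a


def delong_variance(scores, labels, direction: Direction = "higher") -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC)."""
    pos, neg = _split(_oriented(np.asarray(scores, dtype=float), direction),
                      np.asarray(labels))
    a, v_pos, v_neg = _placements(pos, neg)
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("need >= 2 participants per class for a variance estimate")
    var = float(np.var(v_pos, ddof=1) / m + np.var(v_neg, ddof=1) / n)
    return a, max(var, 0.0)


def auc_ci(scores, labels, direction: Direction = "higher",
           level: float = 0.95) -> RocResult:
    """AUC with normal-approximation DeLong CI, clamped to [0, 1]."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    a, var = delong_variance(scores, labels, direction)
    se = float(np.sqrt(var))
    z = float(norm.ppf(0.5 + level / 2.0))
    labels = np.asarray(labels)
    return RocResult(
        auc=a,
        ci_low=max(0.0, a - z * se),
        ci_high=min(1.0, a + z * se),
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
        direction=direction,
        se=se,
        level=level,
    )


def delong_paired_test(
    scores_a,
    scores_b,
    labels,
    directions: tuple[Direction, Direction] = ("higher", "higher"),
) -> tuple[float, float]:
    """Two-sided DeLong test comparing two AUCs on the same participants.

    Returns ``(z, p)`` for ``H0: AUC_a = AUC_b`` where
    ``z = (AUC_a − AUC_b) / sqrt(var(AUC_a − AUC_b))`` and the variance of
    the difference uses the covariance of the shared placement components.
    Identical AUCs with zero variance give ``(0, 1)``.
    """
    sa = _oriented(np.asarray(scores_a, dtype=float), directions[0])
    sb = _oriented(np.asarray(scores_b, dtype=float), directions[1])
    labels = np.asarray(labels)
    if sa.shape != sb.shape:
        raise ValueError("paired score vectors must have equal length")
    pa, na = _split(sa, labels)
    pb, nb = _split(sb, labels)
    auc_a, vpa, vna = _placements(pa, na)
    auc_b, vpb, vnb = _placements(pb, nb)
    m, n = len(pa), len(na)
    if m < 2 or n < 2:
        raise ValueError("need >= 2 participants per class")

    s_pos = np.cov(np.vstack([vpa, vpb]), ddof=1)
    s_neg = np.cov(np.vstack([vna, vnb]), ddof=1)
    cov = s_pos / m + s_neg / n  # 2x2 covariance of (AUC_a, AUC_b)
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    diff = auc_a - auc_b
    if var_diff <= 0.0:
        if abs(diff) < 1e-12:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    z = float(diff / np.sqrt(var_diff))
    p = float(2.0 * norm.sf(abs(z)))
    return z, p


def roc_report(cohort_scores: dict[str, tuple[np.ndarray, Direction]],
               labels) -> "pd.DataFrame":
    """Tabulate AUC + 95% CI for several markers, plus pairwise DeLong p-values.

    ``cohort_scores`` maps a marker label to ``(scores, direction)``; all
    markers must be measured on the same participants.
    """
    import itertools

    import pandas as pd

    rows = []
    for name, (scores, direction) in cohort_scores.items():
        r = auc_ci(scores, labels, direction)
        rows.append({"marker": name, "auc": r.auc, "ci_low": r.ci_low,
                     "ci_high": r.ci_high, "n_pos": r.n_pos, "n_neg": r.n_neg})
    table = pd.DataFrame(rows).set_index("marker")
    for a, b in itertools.combinations(cohort_scores, 2):
        sa, da = cohort_scores[a]
        sb, db = cohort_scores[b]
        _, p = delong_paired_test(sa, sb, labels, (da, db))
        table.loc[a, f"p_vs_{b}"] = p
    return table
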