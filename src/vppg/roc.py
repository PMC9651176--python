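"""Empirical ROC analysis for %PPGmax against the ultrasound reference.

Orientation is fixed to "low score = test positive": a low %PPGmax means
emptying was incomplete during abduction, which is the hemodynamic signature
of a positional venous compression.  Cutoff semantics are strict
less-than — a limb tests positive iff its score is *below* the cutoff — with
operating points placed at every distinct observed score (plus the two
trivial endpoints), matching the convention of standard clinical-statistics
software rather than mid-point cutoffs.

The area under the empirical curve is computed by the trapezoidal rule and
equals the tie-corrected Mann–Whitney statistic P(score_pos < score_neg) +
½·P(tie).  Its standard error uses the Hanley–McNeil closed form

    SE² = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)] / (n₊ n₋),
    Q₁ = A/(2−A),  Q₂ = 2A²/(1+A),

with an exact DeLong covariance estimate available as an option; the
significance test is z = (A − 0.5)/SE against the standard normal.

The operating point reported as optimal minimizes the Euclidean distance on
the unit square from (sensitivity, specificity) to the perfect corner
(1, 1) — the equal-cost choice between false positives and false negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RocPoint",
    "AucResult",
    "empirical_roc",
    "trapezoid_auc",
    "auc_with_se",
    "hanley_mcneil_se",
    "closest_corner_cutoff",
    "plot_roc",
]


@dataclass(frozen=True)
class RocPoint:
    """One operating point: limb tests positive iff score < cutoff."""

    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def distance(self) -> float:
        """Euclidean distance to the perfect (sens, spec) = (1, 1) corner."""
        return float(
            np.hypot(1.0 - self.sensitivity, 1.0 - self.specificity)
        )


@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    z: float
    p: float
    n_pos: int
    n_neg: int
    se_method: str = "hanley-mcneil"


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            "ROC analysis needs at least one positive and one negative limb"
        )
    return pos, neg


def empirical_roc(scores, labels) -> list[RocPoint]:
    """Operating points at every distinct observed score, by direct counting.

    At cutoff c a limb tests positive iff score < c, so
    sensitivity(c) = #{positives < c}/n₊ and specificity(c) = #{negatives ≥
    c}/n₋.  The list is ordered by increasing cutoff from the all-negative
    endpoint (−inf: sens 0, spec 1) to the all-positive endpoint (+inf).
    """
    pos, neg = _split_scores(scores, labels)
    pos_sorted, neg_sorted = np.sort(pos), np.sort(neg)
    cutoffs = np.concatenate(
        ([-np.inf], np.unique(np.concatenate([pos, neg])), [np.inf])
    )
    tp = np.searchsorted(pos_sorted, cutoffs, side="left")
    fp = np.searchsorted(neg_sorted, cutoffs, side="left")
    return [
        RocPoint(
            cutoff=float(c),
            sensitivity=t / len(pos),
            specificity=1.0 - f / len(neg),
        )
        for c, t, f in zip(cutoffs, tp, fp)
    ]


def trapezoid_auc(points: list[RocPoint]) -> float:
    """Trapezoidal area under the curve in (1−specificity, sensitivity)."""
    fpr = np.array([1.0 - p.specificity for p in points])
    tpr = np.array([p.sensitivity for p in points])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def _delong_se(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    # placement values: for each positive, the fraction of negatives it beats
    # (low score = positive, so "beats" means scores below the negative)
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(p < neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos < q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def auc_with_se(scores, labels, se_method: str = "hanley-mcneil") -> AucResult:
    """AUC (tie-corrected Mann–Whitney) with SE and a test against 0.5.

    The area is the trapezoidal integral of :func:`empirical_roc`, which is
    algebraically the Mann–Whitney probability under the low-score-positive
    orientation.  ``se_method`` selects "hanley-mcneil" (default) or
    "delong".
    """
    pos, neg = _split_scores(scores, labels)
    auc = trapezoid_auc(empirical_roc(scores, labels))
    m, n = len(pos), len(neg)
    if se_method == "hanley-mcneil":
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc**2 / (1.0 + auc)
        var = (
            auc * (1.0 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)
        ) / (m * n)
        se = float(np.sqrt(max(var, 0.0)))
    elif se_method == "delong":
        se = _delong_se(pos, neg, auc)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = max(p, np.finfo(float).tiny)  # keep p in (0, 1]
    else:
        z, p = 0.0, 1.0
    return AucResult(
        auc=auc, se=se, z=float(z), p=p, n_pos=m, n_neg=n, se_method=se_method
    )


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil SE for a given area and class sizes (closed form)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def closest_corner_cutoff(points: list[RocPoint]) -> RocPoint:
    """The operating point nearest the perfect (100%, 100%) corner.

    Ties are broken by higher sensitivity, then by lower cutoff.
    """
    if not points:
        raise ValueError("empty ROC point list")
    return min(points, key=lambda p: (p.distance, -p.sensitivity, p.cutoff))


def plot_roc(points: list[RocPoint], ax=None, highlight: RocPoint | None = None):
    """Plot the empirical ROC curve; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    fpr = [1.0 - p.specificity for p in points]
    tpr = [p.sensitivity for p in points]
    order = np.argsort(fpr, kind="stable")
    ax.plot(np.array(fpr)[order], np.array(tpr)[order], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="gray")
    if highlight is not None:
        ax.plot(
            [1.0 - highlight.specificity], [highlight.sensitivity], "o", color="C3"
        )
        ax.annotate(
            f"cutoff {highlight.cutoff:.0f}",
            (1.0 - highlight.specificity, highlight.sensitivity),
            textcoords="offset points",
            xytext=(8, -4),
        )
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    return ax
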