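"""ROC analysis of a continuous score against a binary truth.

The classification rule everywhere is strict: a record tests positive when
its score is strictly greater than the threshold (matching the "z > +2.00
SD" convention of the BMI definitions).  Thresholds are evaluated at the
observed score values plus -inf/+inf sentinels, which is sufficient: the
operating point is constant between consecutive observed values.

AUC is the trapezoidal area over (1 - specificity, sensitivity), which
for this construction equals the Mann-Whitney probability that a random
truth-positive outscores a random truth-negative, counting ties 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

__all__ = ["ROCCurve", "roc_curve", "auc_mann_whitney", "youden_optimal",
           "spearman_rank_corr"]


@dataclass(frozen=True)
class ROCCurve:
    """Operating points of score > threshold, ordered by rising threshold."""

    thresholds: np.ndarray    # -inf, observed unique scores, in rising order
    sensitivity: np.ndarray   # fraction of truth-positives testing positive
    specificity: np.ndarray   # fraction of truth-negatives testing negative
    auc: float
    youden_cutoff: float
    youden_j: float
    youden_tied: bool = False

    @property
    def youden_sensitivity(self) -> float:
        i = int(np.where(self.thresholds == self.youden_cutoff)[0][0])
        return float(self.sensitivity[i])

    @property
    def youden_specificity(self) -> float:
        i = int(np.where(self.thresholds == self.youden_cutoff)[0][0])
        return float(self.specificity[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "youden_j": self.sensitivity + self.specificity - 1.0,
            }
        )

    def summary_dict(self) -> dict:
        return {
            "auc": self.auc,
            "youden_cutoff": self.youden_cutoff,
            "youden_j": self.youden_j,
            "sensitivity_at_cutoff": self.youden_sensitivity,
            "specificity_at_cutoff": self.youden_specificity,
        }


def roc_curve(scores, labels, tie_break: str = "smallest_cutoff") -> ROCCurve:
    """Build the full ROC curve of ``scores`` against boolean ``labels``.

    Requires at least one positive and one negative label.  The Youden
    cutoff maximises J = sensitivity + specificity - 1; exact ties are
    broken toward the smallest cutoff (i.e. maximal sensitivity) by
    default, or toward the largest (maximal specificity) with
    ``tie_break="largest_cutoff"``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise DegenerateInputError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError(
            f"need both classes, got {n_pos} positives / {n_neg} negatives"
        )
    if tie_break not in ("smallest_cutoff", "largest_cutoff"):
        raise DegenerateInputError(f"unknown tie_break {tie_break!r}")

    # thresholds: -inf sentinel (everyone positive) then each unique score;
    # at the largest observed score nobody is positive (strict >), so the
    # (sens 0, spec 1) endpoint is already included and +inf adds nothing new.
    uniq = np.unique(scores)
    thresholds = np.concatenate(([-np.inf], uniq))

    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # cumulative positives/negatives with score <= t for each unique value
    idx = np.searchsorted(s_sorted, uniq, side="right")
    cum_pos = np.concatenate(([0], np.cumsum(l_sorted)))[idx]
    cum_neg = idx - cum_pos

    # score > threshold: positives above threshold = n_pos - cum_pos(t)
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    sens[0], spec[0] = 1.0, 0.0
    sens[1:] = (n_pos - cum_pos) / n_pos
    spec[1:] = cum_neg / n_neg

    # trapezoid over (1-spec, sens); points ordered by falling FPR as the
    # threshold rises, so integrate in reverse
    fpr = 1.0 - spec
    a = float(np.trapezoid(sens[::-1], fpr[::-1]))

    j = sens + spec - 1.0
    jmax = j.max()
    tied_at = np.flatnonzero(np.isclose(j, jmax, rtol=0.0, atol=1e-12))
    pick = tied_at[0] if tie_break == "smallest_cutoff" else tied_at[-1]
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=a,
        youden_cutoff=float(thresholds[pick]),
        youden_j=float(j[pick]),
        youden_tied=len(tied_at) > 1,
    )


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the tie-corrected Mann-Whitney probability.

    P(score_pos > score_neg) + 0.5 P(score_pos = score_neg), computed from
    rank sums.  Serves as an internal consistency identity for the
    trapezoidal AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("need both classes for AUC")
    ranks = stats.rankdata(scores)  # average ranks for ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_optimal(curve: ROCCurve) -> tuple[float, float, float, float]:
    """(cutoff, J, sensitivity, specificity) at the Youden optimum."""
    return (
        curve.youden_cutoff,
        curve.youden_j,
        curve.youden_sensitivity,
        curve.youden_specificity,
    )


def spearman_rank_corr(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("need >= 3 paired values")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateInputError("rank correlation undefined for constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
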