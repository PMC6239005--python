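"""Diagnostic accuracy of a binary test against a binary truth.

The test here is a BMI-for-age criterion (e.g. z > +2) and the truth is
measured excessive fatness, but nothing in this module is specific to
that: it works on any paired binary labels or on a bare 2x2 table.

Confidence intervals for all proportions are Clopper-Pearson exact by
default (this reproduces published one-decimal intervals that score-based
intervals do not); Wilson is available as a first-class alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, PipelineError

__all__ = [
    "ContingencyTable",
    "MetricEstimate",
    "DiagnosticSummary",
    "contingency",
    "proportion_ci",
    "diagnostic_summary",
    "prevalence",
]

CI_METHODS = ("clopper_pearson", "wilson")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; test positives in rows, truth positives in columns."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InvalidParameterError(f"{name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def truth_positive(self) -> int:
        return self.tp + self.fn

    @property
    def truth_negative(self) -> int:
        return self.tn + self.fp

    @property
    def test_positive(self) -> int:
        return self.tp + self.fp

    @property
    def test_negative(self) -> int:
        return self.tn + self.fn


def contingency(truth, test) -> ContingencyTable:
    """Exact 2x2 counts from paired boolean label sequences."""
    truth = np.asarray(truth, dtype=bool)
    test = np.asarray(test, dtype=bool)
    if truth.shape != test.shape:
        raise PipelineError(
            f"label length mismatch: {truth.shape} vs {test.shape}"
        )
    return ContingencyTable(
        tp=int(np.sum(truth & test)),
        fp=int(np.sum(~truth & test)),
        fn=int(np.sum(truth & ~test)),
        tn=int(np.sum(~truth & ~test)),
    )


def proportion_ci(
    k: int,
    n: int,
    method: str = "clopper_pearson",
    level: float = 0.95,
) -> tuple[float, float]:
    """Two-sided CI for a binomial proportion, returned as percentages.

    Clopper-Pearson uses beta quantiles (lower bound exactly 0 when k = 0,
    upper exactly 100 when k = n); Wilson inverts the score test.
    """
    if not (0 <= k <= n) or n <= 0:
        raise InvalidParameterError(f"invalid counts k={k}, n={n}")
    if method not in CI_METHODS:
        raise InvalidParameterError(f"unknown CI method {method!r}")
    alpha = 1.0 - level
    if method == "clopper_pearson":
        lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    else:
        z = stats.norm.ppf(1 - alpha / 2)
        p = k / n
        denom = 1 + z * z / n
        centre = (p + z * z / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        lo, hi = max(centre - half, 0.0), min(centre + half, 1.0)
    return 100.0 * lo, 100.0 * hi


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its CI and the counts it came from (percent scale)."""

    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    @classmethod
    def from_counts(
        cls, k: int, n: int, method: str = "clopper_pearson", level: float = 0.95
    ) -> "MetricEstimate":
        lo, hi = proportion_ci(k, n, method=method, level=level)
        return cls(100.0 * k / n, lo, hi, k, n)

    @classmethod
    def undefined(cls) -> "MetricEstimate":
        # explicit marker for a zero-denominator metric, not NaN arithmetic
        return cls(float("nan"), float("nan"), float("nan"), 0, 0)

    @property
    def is_defined(self) -> bool:
        return self.denominator > 0

    def display(self) -> str:
        if not self.is_defined:
            return "undefined (0 denominator)"
        return (
            f"{_round_half_up(self.estimate)} "
            f"({_round_half_up(self.ci_low)} to {_round_half_up(self.ci_high)})"
        )


def _round_half_up(x: float, digits: int = 1) -> float:
    """Half-up rounding at ``digits`` decimals, matching printed tables."""
    scale = 10 ** digits
    return math.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity, specificity and predictive values for one 2x2 table."""

    table: ContingencyTable
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    prevalence: MetricEstimate
    ci_method: str = "clopper_pearson"

    def as_dict(self) -> dict:
        out = {"tp": self.table.tp, "fp": self.table.fp,
               "fn": self.table.fn, "tn": self.table.tn,
               "ci_method": self.ci_method}
        for name in ("sensitivity", "specificity", "ppv", "npv", "prevalence"):
            m: MetricEstimate = getattr(self, name)
            out[name] = {
                "estimate": m.estimate, "ci_low": m.ci_low, "ci_high": m.ci_high,
                "numerator": m.numerator, "denominator": m.denominator,
            }
        return out


def diagnostic_summary(
    table: ContingencyTable,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> DiagnosticSummary:
    """All four accuracy metrics plus prevalence, with CIs.

    Metrics with a zero denominator come back as explicit undefined
    markers rather than propagating NaNs through arithmetic.
    """

    def metric(k: int, n: int) -> MetricEstimate:
        if n == 0:
            return MetricEstimate.undefined()
        return MetricEstimate.from_counts(k, n, method=ci_method, level=level)

    return DiagnosticSummary(
        table=table,
        sensitivity=metric(table.tp, table.truth_positive),
        specificity=metric(table.tn, table.truth_negative),
        ppv=metric(table.tp, table.test_positive),
        npv=metric(table.tn, table.test_negative),
        prevalence=metric(table.truth_positive, table.n),
        ci_method=ci_method,
    )


def prevalence(
    labels,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> MetricEstimate:
    """Prevalence of a boolean condition in a cohort, with CI."""
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        return MetricEstimate.undefined()
    return MetricEstimate.from_counts(
        int(labels.sum()), int(labels.size), method=ci_method, level=level
    )


def grouped_summaries(
    frame: pd.DataFrame,
    truth_col: str,
    test_col: str,
    group_col: str,
    ci_method: str = "clopper_pearson",
) -> dict:
    """One DiagnosticSummary per level of ``group_col`` (country, region...)."""
    out = {}
    for key, grp in frame.groupby(group_col, sort=True):
        out[key] = diagnostic_summary(
            contingency(grp[truth_col], grp[test_col]), ci_method=ci_method
        )
    return out
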