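"""Quality control for deuterium-dilution measurements.

Four criteria are applied in cascade:

(i)   the two post-dose saliva enrichments must each lie within 2 % of
      their mean (isotopic plateau actually reached);
(ii)  the measured enrichment must be consistent with the child's body
      size — operationalised as a physiological hydration-fraction screen
      (TBW/weight within [0.30, 0.80]) plus an outlier screen on the
      cohort regression of ln(TBW) on ln(height);
(iii) body-fat percentage must be physiological ([3, 60] %) and consistent
      with the BMI z-score (outlier screen on the cohort fit of fat % on
      BMI z);
(iv)  if more than 10 % of a centre's measures fail (i)-(iii), the whole
      centre is excluded.

The numeric bounds for (ii) and (iii) are this package's operationalisation
of screens that protocols describe qualitatively; all are configurable.
Regression screens are fitted once on the pre-filter cohort for
determinism (iterative refitting is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "QCThresholds",
    "QCReport",
    "qc_plateau_agreement",
    "qc_enrichment_range",
    "qc_fat_outlier",
    "qc_centre_exclusion",
    "apply_qc",
    "REASONS",
]

# closed enumeration of exclusion reason codes
REASONS = (
    "incomplete_samples",
    "plateau_disagreement",
    "hydration_ratio_out_of_range",
    "tbw_height_outlier",
    "fat_unphysiological",
    "fat_bmi_mismatch",
    "centre_excluded",
    "no_data",
)


@dataclass(frozen=True)
class QCThresholds:
    """Tunable QC thresholds with the package defaults."""

    plateau_tolerance: float = 0.02          # relative, vs post-dose mean
    hydration_ratio_low: float = 0.30        # TBW / weight lower bound
    hydration_ratio_high: float = 0.80       # TBW / weight upper bound
    fat_pct_low: float = 3.0                 # % body fat physiological floor
    fat_pct_high: float = 60.0               # % body fat physiological ceiling
    max_abs_residual: float = 3.0            # studentized-residual cut, both screens
    centre_failure_rate: float = 0.10        # strict > excludes the centre
    min_records_for_regression: int = 10     # below this, bounds screens only
    refit_after_exclusion: bool = False      # iterative regression refit


def qc_plateau_agreement(
    post_3h: float,
    post_4h: float,
    tolerance: float = 0.02,
) -> bool:
    """Criterion (i): each post-dose sample within ``tolerance`` of their mean."""
    if post_3h is None or post_4h is None or pd.isna(post_3h) or pd.isna(post_4h):
        return False
    mean = 0.5 * (post_3h + post_4h)
    if mean == 0:
        return False
    dev = abs(post_3h - mean) / mean
    return dev <= tolerance  # the two samples deviate symmetrically


def _studentized_outliers(
    y: pd.Series,
    x: pd.Series,
    cut: float,
    min_n: int,
    fit_mask: pd.Series | None = None,
) -> pd.Series:
    """Boolean Series marking |studentized residual| > cut in an OLS fit.

    The regression is fitted only on rows where both variables are finite
    and ``fit_mask`` holds (rows already failing a physiological bounds
    screen are kept out so gross corruption cannot inflate the residual
    scale and mask moderate outliers); only fitted rows are screened —
    other rows are False here because they fail elsewhere.  Cohorts below
    ``min_n`` skip the screen entirely.
    """
    ok = np.isfinite(y) & np.isfinite(x)
    if fit_mask is not None:
        ok &= fit_mask
    out = pd.Series(False, index=y.index)
    if ok.sum() < min_n:
        return out
    model = sm.OLS(y[ok], sm.add_constant(x[ok])).fit()
    resid = OLSInfluence(model).resid_studentized_internal
    out.loc[ok[ok].index] = np.abs(resid) > cut
    return out


def qc_enrichment_range(
    frame: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> pd.DataFrame:
    """Criterion (ii) on a cohort frame with columns tbw, weight_kg, height_m.

    Returns a frame with boolean columns ``ratio_ok`` and ``regression_ok``.
    """
    ratio = frame["tbw"] / frame["weight_kg"]
    ratio_ok = (
        np.isfinite(ratio)
        & (ratio >= thresholds.hydration_ratio_low)
        & (ratio <= thresholds.hydration_ratio_high)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        ln_tbw = np.log(frame["tbw"].where(frame["tbw"] > 0))
        ln_h = np.log(frame["height_m"].where(frame["height_m"] > 0))
    ratio_ok = ratio_ok.fillna(False)
    outlier = _studentized_outliers(
        ln_tbw, ln_h, thresholds.max_abs_residual,
        thresholds.min_records_for_regression, fit_mask=ratio_ok,
    )
    return pd.DataFrame(
        {"ratio_ok": ratio_ok, "regression_ok": ~outlier},
        index=frame.index,
    )


def qc_fat_outlier(
    frame: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> pd.DataFrame:
    """Criterion (iii) on a cohort frame with columns fat_pct, bmi_z.

    Returns boolean columns ``bounds_ok`` and ``mismatch_ok``.
    """
    fat = frame["fat_pct"]
    bounds_ok = (
        np.isfinite(fat)
        & (fat >= thresholds.fat_pct_low)
        & (fat <= thresholds.fat_pct_high)
    )
    bounds_ok = bounds_ok.fillna(False)
    outlier = _studentized_outliers(
        fat, frame["bmi_z"], thresholds.max_abs_residual,
        thresholds.min_records_for_regression, fit_mask=bounds_ok,
    )
    return pd.DataFrame(
        {"bounds_ok": bounds_ok, "mismatch_ok": ~outlier},
        index=frame.index,
    )


def qc_centre_exclusion(
    centre_stats: pd.DataFrame,
    max_rate: float = 0.10,
) -> set:
    """Criterion (iv): centres whose failure rate strictly exceeds ``max_rate``.

    ``centre_stats`` needs columns centre, n_measured, n_failed.  A centre
    with no measured records is excluded (reason ``no_data``).
    """
    excluded = set()
    for row in centre_stats.itertuples():
        if row.n_measured == 0 or (row.n_failed / row.n_measured) > max_rate:
            excluded.add(row.centre)
    return excluded


@dataclass
class QCReport:
    """Per-record flags, per-centre rates and cohort-level exclusion counts."""

    records: pd.DataFrame
    centres: pd.DataFrame
    reason_counts: dict
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    @property
    def n_excluded(self) -> int:
        return int(self.records["excluded"].sum())

    @property
    def excluded_centres(self) -> list:
        return sorted(self.centres.loc[self.centres["centre_excluded"], "centre"])

    def summary(self) -> str:
        lines = ["Quality control summary", "=" * 23]
        lines.append(
            f"records: {len(self.records)}  excluded: {self.n_excluded} "
            f"({100.0 * self.n_excluded / max(len(self.records), 1):.1f}%)"
        )
        lines.append("per-centre failure rates (criteria i-iii):")
        for row in self.centres.itertuples():
            mark = "EXCLUDED" if row.centre_excluded else "retained"
            lines.append(
                f"  {row.centre:<28} {row.n_failed}/{row.n_measured} "
                f"({100.0 * row.failure_rate:.1f}%)  {mark}"
            )
        lines.append("exclusions by reason:")
        for reason in REASONS:
            n = self.reason_counts.get(reason, 0)
            if n:
                lines.append(f"  {reason:<28} {n}")
        return "\n".join(lines)

    def to_files(self, records_path, centres_path) -> None:
        rec = self.records.copy()
        rec["reasons"] = rec["reasons"].map(";".join)
        rec.to_csv(records_path, index=False)
        self.centres.to_csv(centres_path, index=False)


def apply_qc(
    cohort: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[pd.DataFrame, QCReport]:
    """Run criteria (i)-(iv) over a cohort frame and filter it.

    The frame must carry columns id, centre, weight_kg, height_m, enr_3h,
    enr_4h, tbw, fat_pct, bmi_z (tbw/fat_pct may be NaN where samples are
    missing).  Returns the fully passing records from retained centres and
    a complete :class:`QCReport`.
    """
    work = cohort.copy()
    if work.empty:
        records = pd.DataFrame(
            columns=["id", "centre", "criterion_1_pass", "criterion_2_pass",
                     "criterion_3_pass", "excluded", "reasons"]
        )
        centres = pd.DataFrame(
            columns=["centre", "n_measured", "n_failed", "failure_rate",
                     "centre_excluded"]
        )
        return work, QCReport(records, centres, {}, thresholds)

    c1 = work.apply(
        lambda r: qc_plateau_agreement(
            r.get("enr_3h"), r.get("enr_4h"), thresholds.plateau_tolerance
        ),
        axis=1,
    )
    incomplete = ~np.isfinite(work["tbw"])

    def _per_record(frame: pd.DataFrame) -> pd.DataFrame:
        c2 = qc_enrichment_range(frame, thresholds)
        c3 = qc_fat_outlier(frame, thresholds)
        return pd.DataFrame(
            {
                "criterion_1_pass": c1.loc[frame.index] & ~incomplete.loc[frame.index],
                "ratio_ok": c2["ratio_ok"],
                "regression_ok": c2["regression_ok"],
                "bounds_ok": c3["bounds_ok"],
                "mismatch_ok": c3["mismatch_ok"],
            },
            index=frame.index,
        )

    flags = _per_record(work)
    if thresholds.refit_after_exclusion:
        # iterate the regression screens on the surviving records to a fixed point
        for _ in range(10):
            keep = flags.all(axis=1)
            new = _per_record(work[keep])
            merged = flags.copy()
            merged.loc[new.index] = new
            if merged.equals(flags):
                break
            flags = merged

    flags["criterion_2_pass"] = flags["ratio_ok"] & flags["regression_ok"]
    flags["criterion_3_pass"] = flags["bounds_ok"] & flags["mismatch_ok"]
    record_fail = ~(
        flags["criterion_1_pass"]
        & flags["criterion_2_pass"]
        & flags["criterion_3_pass"]
    )

    centre_rows = []
    for centre, grp in work.groupby("centre", sort=True):
        n = len(grp)
        n_failed = int(record_fail.loc[grp.index].sum())
        centre_rows.append(
            {
                "centre": centre,
                "n_measured": n,
                "n_failed": n_failed,
                "failure_rate": n_failed / n if n else float("nan"),
            }
        )
    centres = pd.DataFrame(centre_rows)
    excluded_centres = qc_centre_exclusion(centres, thresholds.centre_failure_rate)
    centres["centre_excluded"] = centres["centre"].isin(excluded_centres)

    in_bad_centre = work["centre"].isin(excluded_centres)
    excluded = record_fail | in_bad_centre

    reasons = []
    for idx in work.index:
        rs = []
        if incomplete.loc[idx]:
            rs.append("incomplete_samples")
        elif not flags.loc[idx, "criterion_1_pass"]:
            rs.append("plateau_disagreement")
        if not flags.loc[idx, "ratio_ok"]:
            rs.append("hydration_ratio_out_of_range")
        if not flags.loc[idx, "regression_ok"]:
            rs.append("tbw_height_outlier")
        if not flags.loc[idx, "bounds_ok"]:
            rs.append("fat_unphysiological")
        if not flags.loc[idx, "mismatch_ok"]:
            rs.append("fat_bmi_mismatch")
        if in_bad_centre.loc[idx]:
            rs.append("centre_excluded")
        reasons.append(rs)

    records = pd.DataFrame(
        {
            "id": work["id"],
            "centre": work["centre"],
            "criterion_1_pass": flags["criterion_1_pass"],
            "criterion_2_pass": flags["criterion_2_pass"],
            "criterion_3_pass": flags["criterion_3_pass"],
            "excluded": excluded,
            "reasons": reasons,
        },
        index=work.index,
    )

    reason_counts: dict = {}
    for rs in reasons:
        for r in rs:
            reason_counts[r] = reason_counts.get(r, 0) + 1

    report = QCReport(
        records=records,
        centres=centres,
        reason_counts=reason_counts,
        thresholds=thresholds,
    )
    return cohort[~excluded].copy(), report
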