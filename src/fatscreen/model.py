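"""End-to-end screening analysis as a model / results pair.

:class:`ObesityScreening` is built from a cohort and a growth reference;
``fit()`` runs z-scoring, deuterium-dilution body composition, the QC
cascade, classification, diagnostic accuracy at each configured BMI-z
cutoff, and the ROC/Youden analysis, returning an
:class:`ObesityScreeningResults` with the estimates, their confidence
intervals, QC diagnostics and a printable summary table.

``summarize_counts`` is the shortcut for a precomputed 2x2 table, which
is how published cross-classifications are re-analysed directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .diagnostics import (
    ContingencyTable,
    DiagnosticSummary,
    MetricEstimate,
    contingency,
    diagnostic_summary,
    _round_half_up,
)
from .errors import DegenerateInputError, PipelineError
from .growth import LMSReference, bmi, bmi_for_age_z
from .isotope import (
    FAT_PCT_THRESHOLDS,
    HydrationTable,
    compute_dose,
    plateau_enrichment,
    total_body_water,
    body_composition,
)
from .qc import QCReport, QCThresholds, apply_qc
from .roc import ROCCurve, roc_curve, spearman_rank_corr

__all__ = [
    "ObesityScreening",
    "ObesityScreeningResults",
    "summarize_counts",
    "DEFAULT_REGIONS",
]

#: geographic sub-grouping of the study countries (overridable)
DEFAULT_REGIONS = {
    "Ghana": "sub-Saharan Africa",
    "Kenya": "sub-Saharan Africa",
    "Namibia": "sub-Saharan Africa",
    "Senegal": "sub-Saharan Africa",
    "United Republic of Tanzania": "sub-Saharan Africa",
    "Morocco": "North Africa",
    "Tunisia": "North Africa",
    "Mauritius": "African island",
}


def summarize_counts(
    tp: int, fp: int, fn: int, tn: int, ci_method: str = "clopper_pearson"
) -> DiagnosticSummary:
    """Diagnostic metrics straight from a bare 2x2 table."""
    return diagnostic_summary(ContingencyTable(tp, fp, fn, tn), ci_method=ci_method)


class ObesityScreening:
    """Screening-accuracy model for one cohort.

    Parameters
    ----------
    cohort
        Cohort frame in the interchange layout (id, centre, sex,
        age_months, weight_kg, height_cm, dose_g, enr_pre, enr_3h,
        enr_4h).  Heights in cm; sex in any accepted encoding.
    reference
        LMS growth reference for BMI-for-age z-scores.
    hydration
        Hydration-of-fat-free-mass table; packaged defaults if omitted.
    qc_thresholds
        QC screen configuration.
    ci_method
        "clopper_pearson" (default) or "wilson".
    cutoffs
        BMI-z cutoffs to tabulate; the Youden-optimal cutoff is always
        appended.
    region_map
        centre -> region grouping; defaults to the three-region split.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        reference: LMSReference,
        hydration: HydrationTable | None = None,
        qc_thresholds: QCThresholds | None = None,
        ci_method: str = "clopper_pearson",
        cutoffs: tuple = (2.0, 1.0),
        region_map: dict | None = None,
    ) -> None:
        self.cohort = fio.normalize_cohort(cohort) if "height_m" not in cohort else cohort.copy()
        self.reference = reference
        self.hydration = hydration or HydrationTable.default()
        self.qc_thresholds = qc_thresholds or QCThresholds()
        self.ci_method = ci_method
        if not cutoffs:
            raise PipelineError("cutoff list must be non-empty")
        self.cutoffs = tuple(cutoffs)
        self.region_map = dict(region_map or DEFAULT_REGIONS)

    @classmethod
    def from_files(
        cls,
        cohort_path,
        reference_path,
        hydration_path=None,
        **kwargs,
    ) -> "ObesityScreening":
        cohort = fio.read_cohort(cohort_path)
        reference = LMSReference.from_file(reference_path)
        hydration = (
            HydrationTable.from_file(hydration_path) if hydration_path else None
        )
        return cls(cohort, reference, hydration=hydration, **kwargs)

    # ------------------------------------------------------------------

    def _stage_measures(self) -> tuple[pd.DataFrame, dict]:
        """Per-record BMI, z-score and body composition; reasons for drops."""
        work = self.cohort.copy()
        drop_reasons: dict[str, int] = {}

        def drop(mask: pd.Series, reason: str) -> None:
            n = int(mask.sum())
            if n:
                drop_reasons[reason] = drop_reasons.get(reason, 0) + n

        valid = pd.Series(True, index=work.index)
        bad_sex = work["sex"].isna()
        drop(bad_sex, "unknown_sex")
        valid &= ~bad_sex
        bad_size = ~(work["weight_kg"] > 0) | ~(work["height_m"] > 0)
        drop(bad_size & valid, "invalid_anthropometry")
        valid &= ~bad_size

        work["age_years"] = work["age_months"] // 12
        work["age_eligible"] = work["age_years"].between(8, 11)

        bmis = np.full(len(work), np.nan)
        zs = np.full(len(work), np.nan)
        for i, (idx, row) in enumerate(work.iterrows()):
            if not valid.loc[idx]:
                continue
            b = bmi(row["weight_kg"], row["height_m"])
            bmis[i] = b
            try:
                zs[i] = bmi_for_age_z(
                    row["sex"], row["age_months"], b, self.reference
                )
            except Exception:
                zs[i] = np.nan
        work["bmi"] = bmis
        work["bmi_z"] = zs
        no_z = valid & ~np.isfinite(work["bmi_z"])
        drop(no_z, "age_outside_reference")
        valid &= ~no_z

        tbw = np.full(len(work), np.nan)
        fat = np.full(len(work), np.nan)
        fmi = np.full(len(work), np.nan)
        ffmi = np.full(len(work), np.nan)
        ffm = np.full(len(work), np.nan)
        for i, (idx, row) in enumerate(work.iterrows()):
            if not valid.loc[idx]:
                continue
            try:
                dose = row["dose_g"]
                if not np.isfinite(dose):
                    dose = compute_dose(row["weight_kg"])
                delta = plateau_enrichment(
                    row["enr_pre"], row["enr_3h"], row["enr_4h"]
                )
                t = total_body_water(dose, delta)
                comp = body_composition(
                    t,
                    row["weight_kg"],
                    row["height_m"],
                    row["sex"],
                    row["age_years"],
                    self.hydration,
                )
            except Exception:
                continue  # left NaN; QC flags it as incomplete
            tbw[i] = t
            fat[i] = comp.fat_pct
            fmi[i] = comp.fmi
            ffmi[i] = comp.ffmi
            ffm[i] = comp.ffm
        work["tbw"] = tbw
        work["fat_pct"] = fat
        work["fmi"] = fmi
        work["ffmi"] = ffmi
        work["ffm"] = ffm
        work["stage_valid"] = valid
        return work, drop_reasons

    def fit(self) -> "ObesityScreeningResults":
        """Run the full analysis and return the results object."""
        work, drop_reasons = self._stage_measures()
        measurable = work[work["stage_valid"]].copy()

        filtered, qc_report = apply_qc(measurable, self.qc_thresholds)

        # classification on the QC-retained records
        thr = filtered["sex"].map(FAT_PCT_THRESHOLDS)
        filtered["fat_excess"] = filtered["fat_pct"] > thr
        filtered["bmi_obese"] = filtered["bmi_z"] > 2.0
        filtered["bmi_overweight"] = filtered["bmi_z"] > 1.0
        filtered["region"] = filtered["centre"].map(
            lambda c: self.region_map.get(c, "other")
        )

        flow = {
            "recruited": len(work),
            "measurable": len(measurable),
            "qc_retained": len(filtered),
            "dropped_at_ingest": drop_reasons,
            "qc_excluded": qc_report.n_excluded,
            "excluded_centres": qc_report.excluded_centres,
        }

        if filtered.empty:
            return ObesityScreeningResults(
                model=self, data=filtered, qc_report=qc_report, flow=flow,
                empty=True,
            )

        prev = {
            name: MetricEstimate.from_counts(
                int(filtered[col].sum()), len(filtered), method=self.ci_method
            )
            for name, col in (
                ("fat_excess", "fat_excess"),
                ("bmi_obese", "bmi_obese"),
                ("bmi_overweight", "bmi_overweight"),
            )
        }

        # ROC of BMI-z for fat-excess; Youden cutoff joins the panel
        curve = None
        try:
            curve = roc_curve(
                filtered["bmi_z"].to_numpy(), filtered["fat_excess"].to_numpy()
            )
        except DegenerateInputError:
            pass

        cutoffs = list(self.cutoffs)
        if curve is not None and np.isfinite(curve.youden_cutoff):
            cutoffs.append(curve.youden_cutoff)

        panel = {}
        by_country = {}
        by_region = {}
        for cut in cutoffs:
            test = filtered["bmi_z"] > cut
            panel[cut] = diagnostic_summary(
                contingency(filtered["fat_excess"], test), ci_method=self.ci_method
            )
            by_country[cut] = {
                c: diagnostic_summary(
                    contingency(g["fat_excess"], g["bmi_z"] > cut),
                    ci_method=self.ci_method,
                )
                for c, g in filtered.groupby("centre", sort=True)
            }
            by_region[cut] = {
                r: diagnostic_summary(
                    contingency(g["fat_excess"], g["bmi_z"] > cut),
                    ci_method=self.ci_method,
                )
                for r, g in filtered.groupby("region", sort=True)
            }

        # country-level rank correlation of median BMI-z vs median fat %
        spearman_rho = float("nan")
        med = filtered.groupby("centre")[["bmi_z", "fat_pct"]].median()
        if len(med) >= 3:
            try:
                spearman_rho = spearman_rank_corr(
                    med["bmi_z"].to_numpy(), med["fat_pct"].to_numpy()
                )
            except DegenerateInputError:
                pass

        descriptives = self._descriptives(filtered)

        return ObesityScreeningResults(
            model=self,
            data=filtered,
            qc_report=qc_report,
            flow=flow,
            prevalence=prev,
            cutoff_panel=panel,
            by_country=by_country,
            by_region=by_region,
            roc=curve,
            spearman_rho=spearman_rho,
            descriptives=descriptives,
        )

    @staticmethod
    def _descriptives(frame: pd.DataFrame) -> pd.DataFrame:
        """Median (IQR) of the key measures by country and sex."""
        rows = []
        groups = [("Total", frame)] + [
            (c, g) for c, g in frame.groupby("centre", sort=True)
        ]
        for centre, grp in groups:
            for sex, sub in (
                ("boys", grp[grp["sex"] == "male"]),
                ("girls", grp[grp["sex"] == "female"]),
                ("all", grp),
            ):
                if sub.empty:
                    continue
                row = {"centre": centre, "sex": sex, "n": len(sub)}
                for col, label in (
                    ("age_years", "age_yr"),
                    ("bmi_z", "bmi_z"),
                    ("fat_pct", "fat_pct"),
                    ("fmi", "fmi"),
                    ("ffmi", "ffmi"),
                ):
                    q = sub[col].quantile([0.25, 0.5, 0.75])
                    row[f"{label}_median"] = q.loc[0.5]
                    row[f"{label}_q1"] = q.loc[0.25]
                    row[f"{label}_q3"] = q.loc[0.75]
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ObesityScreeningResults:
    """Fitted screening analysis: estimates, CIs, diagnostics, exports."""

    model: ObesityScreening
    data: pd.DataFrame
    qc_report: QCReport
    flow: dict
    prevalence: dict = field(default_factory=dict)
    cutoff_panel: dict = field(default_factory=dict)
    by_country: dict = field(default_factory=dict)
    by_region: dict = field(default_factory=dict)
    roc: ROCCurve | None = None
    spearman_rho: float = float("nan")
    descriptives: pd.DataFrame | None = None
    empty: bool = False

    @property
    def auc(self) -> float:
        return self.roc.auc if self.roc is not None else float("nan")

    @property
    def youden_cutoff(self) -> float:
        return self.roc.youden_cutoff if self.roc is not None else float("nan")

    def summary(self) -> str:
        """Human-readable analysis summary (counts, metrics, ROC)."""
        if self.empty:
            return "Obesity screening analysis: EMPTY (all records excluded)"
        lines = ["Obesity screening analysis", "=" * 26]
        f = self.flow
        lines.append(
            f"records: {f['recruited']} recruited -> {f['measurable']} measurable "
            f"-> {f['qc_retained']} QC-retained"
        )
        if f["excluded_centres"]:
            lines.append(f"centres excluded by QC: {', '.join(f['excluded_centres'])}")
        lines.append("")
        lines.append("prevalence (% of retained cohort):")
        for name, m in self.prevalence.items():
            lines.append(f"  {name:<16} {m.display()}  [{m.numerator}/{m.denominator}]")
        lines.append("")
        for cut, summ in self.cutoff_panel.items():
            lines.append(f"BMI z > {_round_half_up(cut, 2):+.2f} SD vs excessive fatness:")
            for metric in ("sensitivity", "specificity", "ppv", "npv"):
                m: MetricEstimate = getattr(summ, metric)
                lines.append(
                    f"  {metric:<12} {m.display()}  [{m.numerator}/{m.denominator}]"
                )
        if self.roc is not None:
            lines.append("")
            lines.append(
                f"ROC: AUC {self.auc:.3f}; Youden-optimal cutoff "
                f"z = {self.youden_cutoff:+.2f} SD "
                f"(J = {self.roc.youden_j:.3f})"
            )
        if np.isfinite(self.spearman_rho):
            lines.append(
                f"country-level Spearman rho (median BMI-z vs median fat %): "
                f"{self.spearman_rho:.2f}"
            )
        return "\n".join(lines)

    def metrics_dict(self) -> dict:
        out = {
            "flow": self.flow,
            "ci_method": self.model.ci_method,
            "prevalence": {
                k: {
                    "estimate": m.estimate,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "numerator": m.numerator,
                    "denominator": m.denominator,
                }
                for k, m in self.prevalence.items()
            },
            "cutoffs": {
                f"{cut:+.4f}": summ.as_dict()
                for cut, summ in self.cutoff_panel.items()
            },
            "spearman_rho": self.spearman_rho,
        }
        if self.roc is not None:
            out["roc"] = self.roc.summary_dict()
        return out

    def save(self, outdir) -> None:
        """Write the report files: descriptives, QC, cross-tables, metrics, ROC."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.descriptives is not None:
            self.descriptives.to_csv(outdir / "descriptives.csv", index=False)
        self.qc_report.to_files(
            outdir / "qc_records.csv", outdir / "qc_centres.csv"
        )
        rows = []
        for cut, groups in self.by_country.items():
            for centre, summ in groups.items():
                t = summ.table
                rows.append(
                    {
                        "cutoff": cut,
                        "group": centre,
                        "tp": t.tp,
                        "fp": t.fp,
                        "fn": t.fn,
                        "tn": t.tn,
                    }
                )
        if rows:
            pd.DataFrame(rows).sort_values(["cutoff", "group"]).to_csv(
                outdir / "crossclass_country.csv", index=False
            )
        with open(outdir / "metrics.json", "wt", encoding="utf-8") as fh:
            json.dump(self.metrics_dict(), fh, indent=2, default=float)
        if self.roc is not None:
            self.roc.to_frame().to_csv(outdir / "roc_curve.csv", index=False)
        with open(outdir / "summary.txt", "wt", encoding="utf-8") as fh:
            fh.write(self.summary() + "\n")
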