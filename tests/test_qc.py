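"""The four-criterion QC cascade and centre exclusion rule."""

import numpy as np
import pandas as pd
import pytest

from fatscreen import (
    GeneratorConfig,
    ObesityScreening,
    QCThresholds,
    apply_qc,
    generate_cohort,
    inject_qc_failures,
)
from fatscreen.qc import (
    qc_centre_exclusion,
    qc_enrichment_range,
    qc_fat_outlier,
    qc_plateau_agreement,
)


class TestPlateauAgreement:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (500.0, 510.0, True),   # 0.99% deviation
            (480.0, 520.0, False),  # 4% deviation
            (500.0, 500.0, True),   # identical samples
            (490.0, 510.0, True),   # exactly 2% -> inclusive pass
        ],
    )
    def test_two_percent_rule(self, a, b, expected):
        assert qc_plateau_agreement(a, b) is expected

    def test_zero_mean_fails(self):
        assert qc_plateau_agreement(0.0, 0.0) is False

    def test_missing_sample_fails(self):
        assert qc_plateau_agreement(float("nan"), 500.0) is False


class TestEnrichmentRange:
    def test_hydration_fraction_bounds_small_cohort(self):
        # below the regression minimum only the ratio screen applies
        frame = pd.DataFrame(
            {
                "tbw": [18.0, 27.0, 5.0],
                "weight_kg": [30.0, 30.0, 30.0],
                "height_m": [1.35, 1.35, 1.35],
            }
        )
        out = qc_enrichment_range(frame)
        assert out["ratio_ok"].tolist() == [True, False, False]
        assert out["regression_ok"].all()  # screen skipped, nothing flagged

    def test_gross_tbw_outlier_flagged_by_regression(self, default_cohort, lms_ref):
        cohort, _ = default_cohort
        work, _ = ObesityScreening(cohort, lms_ref)._stage_measures()
        idx = work.index[5]
        work.loc[idx, "tbw"] *= 10.0
        out = qc_enrichment_range(work)
        assert not (out.loc[idx, "ratio_ok"] and out.loc[idx, "regression_ok"])
        # everyone else still passes
        others = out.drop(index=idx)
        assert others.all().all()


class TestFatOutlier:
    def test_unphysiological_fat_fails_bounds(self):
        frame = pd.DataFrame({"fat_pct": [-2.0, 22.0, 65.0], "bmi_z": [0.0, 0.0, 0.0]})
        out = qc_fat_outlier(frame)
        assert out["bounds_ok"].tolist() == [False, True, False]

    def test_fat_bmi_mismatch_flagged_in_cohort(self, default_cohort, lms_ref):
        cohort, _ = default_cohort
        work, _ = ObesityScreening(cohort, lms_ref)._stage_measures()
        idx = work.index[10]
        work.loc[idx, "fat_pct"] = 55.0
        work.loc[idx, "bmi_z"] = -2.0
        out = qc_fat_outlier(work)
        assert not out.loc[idx, "mismatch_ok"]

    def test_typical_record_passes(self, default_cohort, lms_ref):
        cohort, _ = default_cohort
        work, _ = ObesityScreening(cohort, lms_ref)._stage_measures()
        out = qc_fat_outlier(work)
        assert out.all(axis=1).all()


class TestCentreExclusion:
    @pytest.mark.parametrize(
        "n_failed, n, expected",
        [(16, 150, True), (15, 150, False), (0, 150, False)],  # strict > 10%
    )
    def test_strict_ten_percent_rule(self, n_failed, n, expected):
        stats = pd.DataFrame(
            {"centre": ["X"], "n_measured": [n], "n_failed": [n_failed]}
        )
        assert (("X" in qc_centre_exclusion(stats)) is expected)

    def test_empty_centre_excluded(self):
        stats = pd.DataFrame({"centre": ["X"], "n_measured": [0], "n_failed": [0]})
        assert "X" in qc_centre_exclusion(stats)


class TestApplyQC:
    def test_clean_cohort_is_untouched(self, fitted):
        assert fitted.qc_report.n_excluded == 0
        assert fitted.flow["qc_retained"] == fitted.flow["measurable"]

    def test_plateau_injections_match_ledger_exactly(self, default_cohort, lms_ref):
        cohort, ledger = default_cohort
        corrupted, led2 = inject_qc_failures(cohort, ledger, {"plateau": 0.02}, seed=7)
        res = ObesityScreening(corrupted, lms_ref).fit()
        rep = res.qc_report
        excluded = sorted(rep.records.loc[rep.records.excluded, "id"])
        assert excluded == led2.injected_ids
        assert not rep.excluded_centres

    def test_partition_identity(self, default_cohort, lms_ref):
        cohort, ledger = default_cohort
        corrupted, _ = inject_qc_failures(cohort, ledger, {"plateau": 0.03}, seed=9)
        model = ObesityScreening(corrupted, lms_ref)
        work, _ = model._stage_measures()
        filtered, report = apply_qc(work[work["stage_valid"]])
        assert len(filtered) + report.n_excluded == len(work)

    def test_row_order_invariance(self, default_cohort, lms_ref):
        cohort, ledger = default_cohort
        corrupted, _ = inject_qc_failures(cohort, ledger, {"plateau": 0.02}, seed=7)
        model = ObesityScreening(corrupted, lms_ref)
        work, _ = model._stage_measures()
        work = work[work["stage_valid"]]
        _, rep1 = apply_qc(work)
        shuffled = work.sample(frac=1.0, random_state=3)
        _, rep2 = apply_qc(shuffled)
        ids1 = set(rep1.records.loc[rep1.records.excluded, "id"])
        ids2 = set(rep2.records.loc[rep2.records.excluded, "id"])
        assert ids1 == ids2

    def test_overloaded_centre_fully_excluded(self, default_cohort, lms_ref):
        cohort, ledger = default_cohort
        corrupted, _ = inject_qc_failures(
            cohort, ledger, {"plateau": {"Kenya": 0.15}}, seed=11
        )
        res = ObesityScreening(corrupted, lms_ref).fit()
        rep = res.qc_report
        assert rep.excluded_centres == ["Kenya"]
        kenya = rep.records[rep.records.centre == "Kenya"]
        assert kenya.excluded.all()
        # passing records in the excluded centre carry the centre reason
        passing = kenya[kenya.criterion_1_pass & kenya.criterion_2_pass
                        & kenya.criterion_3_pass]
        assert all("centre_excluded" in r for r in passing.reasons)

    def test_exact_boundary_centre_retained(self, default_cohort, lms_ref):
        # corrupt exactly 15/150 records (10.0%) in one centre: retained
        cohort, _ = default_cohort
        corrupted = cohort.copy()
        ghana = corrupted.index[corrupted.centre == "Ghana"][:15]
        for idx in ghana:
            pre = corrupted.at[idx, "enr_pre"]
            corrupted.at[idx, "enr_3h"] = pre + (corrupted.at[idx, "enr_3h"] - pre) * 1.10
        res = ObesityScreening(corrupted, lms_ref).fit()
        rep = res.qc_report
        stats = rep.centres.set_index("centre").loc["Ghana"]
        assert stats.n_failed == 15 and stats.n_measured == 150
        assert not stats.centre_excluded

    def test_incomplete_samples_reported(self, small_config, lms_ref):
        cohort, _ = generate_cohort(small_config, seed=4, reference=lms_ref)
        cohort = cohort.copy()
        cohort.loc[cohort.index[:5], "enr_3h"] = np.nan
        res = ObesityScreening(cohort, lms_ref).fit()
        assert res.qc_report.reason_counts.get("incomplete_samples", 0) == 5

    def test_thresholds_are_configurable(self, default_cohort, lms_ref):
        cohort, _ = default_cohort
        tight = QCThresholds(hydration_ratio_low=0.55, hydration_ratio_high=0.60)
        res = ObesityScreening(cohort, lms_ref, qc_thresholds=tight).fit()
        assert res.qc_report.n_excluded > 0
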