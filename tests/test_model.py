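"""End-to-end model object, report consistency, ingest rules, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from fatscreen import (
    GeneratorConfig,
    ObesityScreening,
    generate_cohort,
    summarize_counts,
)
from fatscreen.cli import main as cli_main
from fatscreen.diagnostics import diagnostic_summary, ContingencyTable


class TestReportConsistency:
    def test_every_metric_equals_its_counts(self, fitted):
        for summ in fitted.cutoff_panel.values():
            for name in ("sensitivity", "specificity", "ppv", "npv"):
                m = getattr(summ, name)
                if m.is_defined:
                    assert m.estimate == pytest.approx(
                        100 * m.numerator / m.denominator, abs=1e-12
                    )

    def test_flow_accounting_adds_up(self, fitted):
        f = fitted.flow
        assert f["qc_retained"] == f["measurable"] - f["qc_excluded"]
        assert f["recruited"] >= f["measurable"]

    def test_panel_contains_standard_and_youden_cutoffs(self, fitted):
        cuts = list(fitted.cutoff_panel)
        assert 2.0 in cuts and 1.0 in cuts
        assert fitted.youden_cutoff in cuts

    def test_region_tables_aggregate_country_tables(self, fitted):
        for cut, regions in fitted.by_region.items():
            countries = fitted.by_country[cut]
            region_of = fitted.model.region_map
            for region, summ in regions.items():
                members = [c for c in countries if region_of.get(c, "other") == region]
                tp = sum(countries[c].table.tp for c in members)
                assert summ.table.tp == tp

    def test_descriptives_cover_all_centres(self, fitted):
        centres = set(fitted.descriptives["centre"])
        assert "Total" in centres
        assert set(fitted.data["centre"].unique()) <= centres

    def test_save_is_idempotent(self, fitted, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        fitted.save(d1)
        fitted.save(d2)
        for name in ("metrics.json", "descriptives.csv", "roc_curve.csv",
                     "qc_records.csv", "qc_centres.csv", "summary.txt"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_summary_prints_key_quantities(self, fitted):
        text = fitted.summary()
        assert "sensitivity" in text and "AUC" in text
        assert "prevalence" in text


class TestCountsMode:
    def test_matches_diagnostic_summary(self):
        direct = diagnostic_summary(ContingencyTable(8, 2, 4, 16))
        via_counts = summarize_counts(8, 2, 4, 16)
        assert via_counts.sensitivity.estimate == direct.sensitivity.estimate
        assert via_counts.npv.ci_low == direct.npv.ci_low


class TestNoiseFreeLedgerAgreement:
    def test_contingency_equals_ledger_truth(self, lms_ref):
        config = GeneratorConfig(
            centres={"Alpha": (70, -0.2), "Beta": (70, 0.3)},
            enrichment_noise_sd=0.0,
        )
        cohort, ledger = generate_cohort(config, seed=21, reference=lms_ref)
        res = ObesityScreening(cohort, lms_ref).fit()
        truth = ledger.frame
        t = res.cutoff_panel[2.0].table
        assert t.tp == int((truth.true_fat_excess & truth.true_bmi_obese).sum())
        assert t.fn == int((truth.true_fat_excess & ~truth.true_bmi_obese).sum())
        assert t.fp == int((~truth.true_fat_excess & truth.true_bmi_obese).sum())


class TestIngest:
    def _tiny_cohort(self):
        return pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "centre": ["X", "X", "X"],
                "sex": ["M", "2", "unknown"],
                "age_months": [110, 120, 115],
                "weight_kg": [30.0, 35.0, 32.0],
                "height_cm": [135.0, 140.0, 138.0],
            }
        )

    def test_sex_encodings_and_height_conversion(self, lms_ref):
        model = ObesityScreening(self._tiny_cohort(), lms_ref)
        work, reasons = model._stage_measures()
        assert work.loc[0, "sex"] == "male"
        assert work.loc[1, "sex"] == "female"
        assert work.loc[0, "height_m"] == pytest.approx(1.35)
        assert reasons.get("unknown_sex") == 1
        assert not work.loc[2, "stage_valid"]

    def test_all_excluded_yields_empty_marker(self, lms_ref):
        cohort = self._tiny_cohort()
        cohort["sex"] = "unknown"
        res = ObesityScreening(cohort, lms_ref).fit()
        assert res.empty
        assert "EMPTY" in res.summary()

    def test_missing_enrichments_dropped_with_reason_not_crash(self, lms_ref):
        res = ObesityScreening(self._tiny_cohort(), lms_ref).fit()
        assert res.empty  # no record has isotope data
        assert res.qc_report.reason_counts.get("incomplete_samples", 0) == 2

    def test_files_round_trip(self, lms_ref, small_config, tmp_path):
        cohort, _ = generate_cohort(small_config, seed=3, reference=lms_ref)
        cohort_path = tmp_path / "cohort.csv"
        ref_path = tmp_path / "ref.csv"
        cohort.to_csv(cohort_path, index=False)
        lms_ref.to_file(ref_path)
        model = ObesityScreening.from_files(cohort_path, ref_path)
        res = model.fit()
        direct = ObesityScreening(cohort, lms_ref).fit()
        assert res.prevalence["fat_excess"].estimate == pytest.approx(
            direct.prevalence["fat_excess"].estimate
        )


class TestCLI:
    def test_simulate_then_analyze(self, tmp_path):
        runner = CliRunner()
        cfg = GeneratorConfig(centres={"Alpha": (60, -0.3), "Beta": (60, 0.4)})
        cfg_path = tmp_path / "cfg.json"
        cfg.to_file(cfg_path)
        simdir = tmp_path / "sim"
        result = runner.invoke(
            cli_main,
            ["simulate", "--config", str(cfg_path), "--seed", "7",
             "--out", str(simdir)],
        )
        assert result.exit_code == 0, result.output
        assert (simdir / "cohort.csv").exists()
        assert (simdir / "ledger.csv").exists()

        outdir = tmp_path / "report"
        result = runner.invoke(
            cli_main,
            ["analyze", str(simdir / "cohort.csv"),
             str(simdir / "lms_reference.csv"), "--out", str(outdir)],
        )
        assert result.exit_code == 0, result.output
        metrics = json.loads((outdir / "metrics.json").read_text())
        assert "prevalence" in metrics and "roc" in metrics

    def test_counts_subcommand(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["counts", "8", "2", "4", "16"])
        assert result.exit_code == 0
        assert "sensitivity" in result.output
        assert "66.7" in result.output  # 8/12 to one decimal

    def test_zscore_subcommand(self, lms_ref, small_config, tmp_path):
        from fatscreen import generate_cohort as gen
        cohort, ledger = gen(small_config, seed=9, reference=lms_ref)
        cohort_path, ref_path = tmp_path / "c.csv", tmp_path / "r.csv"
        cohort.to_csv(cohort_path, index=False)
        lms_ref.to_file(ref_path)
        out_path = tmp_path / "z.csv"
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["zscore", str(cohort_path), str(ref_path),
                       "--out", str(out_path)]
        )
        assert result.exit_code == 0, result.output
        out = pd.read_csv(out_path)
        np.testing.assert_allclose(
            out["bmi_z"], ledger.frame["true_bmi_z"], atol=1e-9
        )
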