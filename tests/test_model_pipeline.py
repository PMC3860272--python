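"""Model/Results surface, CSV round-trips, validation and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from alkox import (
    AlkaneCouplingModel,
    RunConfig,
    run_pipeline,
    scenario_paper_defaults,
    simulate_incubation,
)
from alkox.cli import main as cli_main
from alkox.io import (
    dataset_to_csvs,
    read_assays_csv,
    read_isotopes_csv,
    read_timeseries_csv,
    validate_csv,
)


@pytest.fixture(scope="module")
def noiseless_results(noiseless_dataset):
    return AlkaneCouplingModel.from_dataset(noiseless_dataset).fit()


class TestModelFit:
    def test_noiseless_fit_recovers_truth_rates_exactly(self, noiseless_dataset,
                                                        noiseless_results):
        truth = noiseless_dataset.truth["per_treatment"]
        for treatment, summary in noiseless_results.rate_summaries.items():
            assert summary["rate_mean"] == pytest.approx(
                truth[treatment]["rate"], abs=1e-9)

    def test_noiseless_corrected_ratios_equal_ground_truth_algebra(
            self, noiseless_dataset, noiseless_results):
        truth = noiseless_dataset.truth["per_treatment"]
        for r in noiseless_results.reports:
            expected = truth[r.treatment]["rate"] / truth[r.treatment]["corrected_srr"]
            assert r.observed_ratio_corrected == pytest.approx(expected, rel=1e-9)

    def test_summary_mentions_all_treatments(self, noiseless_results):
        text = noiseless_results.summary()
        for treatment in ("methane", "ethane", "propane", "butane", "N2"):
            assert treatment in text

    def test_table4_has_one_row_per_alkane_treatment(self, noiseless_results):
        df = noiseless_results.table4()
        assert sorted(df["treatment"]) == ["butane", "ethane", "methane", "propane"]
        assert not df["observed_ratio_total"].isna().any()

    def test_missing_control_assay_rejected(self, noiseless_dataset):
        assays = {t: a for t, a in noiseless_dataset.tracer_assays.items()
                  if t != "N2"}
        with pytest.raises(KeyError, match="N2"):
            AlkaneCouplingModel(noiseless_dataset.time_series, assays)

    def test_end_to_end_recovery_with_noise_reproduces_ratio_structure(self):
        """With 4% measurement noise and counting noise, the mean corrected
        ratios across seeds stay within 20% of the noiseless values."""
        expected = {"methane": 263 / 203, "ethane": 168 / 236,
                    "propane": 354 / 152, "butane": 125 / 125}
        sums = {t: [] for t in expected}
        for seed in range(25):
            ds = simulate_incubation(scenario_paper_defaults(seed=300 + seed))
            res = AlkaneCouplingModel.from_dataset(ds).fit()
            for r in res.reports:
                if np.isfinite(r.observed_ratio_corrected):
                    sums[r.treatment].append(r.observed_ratio_corrected)
        for treatment, values in sums.items():
            assert np.mean(values) == pytest.approx(expected[treatment], rel=0.2)


class TestCsvRoundTrip:
    def test_dataset_bundle_round_trips(self, tmp_path, noiseless_dataset):
        paths = dataset_to_csvs(noiseless_dataset, tmp_path)
        series = read_timeseries_csv(paths["timeseries"])
        assert len(series) == len(noiseless_dataset.time_series)
        back = {(ts.treatment, ts.replicate_id): ts for ts in series}
        for ts in noiseless_dataset.time_series:
            got = back[(ts.treatment, ts.replicate_id)]
            assert np.allclose(got.values, ts.values)
        assays = read_assays_csv(paths["assays"])
        assert assays["methane"][0].a == noiseless_dataset.tracer_assays["methane"].a
        isotopes = read_isotopes_csv(paths["isotopes"])
        inp = noiseless_dataset.isotopes["propane"]["balance_input"]
        assert isotopes["propane"].delta_dic_Tf == pytest.approx(inp.delta_dic_Tf)
        truth = json.loads(paths["truth"].read_text())
        assert truth["config"]["seed"] == noiseless_dataset.truth["config"]["seed"]


class TestValidation:
    def test_well_formed_fixture_has_no_diagnostics(self, tmp_path, noiseless_dataset):
        paths = dataset_to_csvs(noiseless_dataset, tmp_path)
        assert validate_csv(paths["timeseries"], "timeseries") == []
        assert validate_csv(paths["assays"], "assays") == []
        assert validate_csv(paths["isotopes"], "isotopes") == []

    def test_negative_concentration_flagged_at_its_row(self, tmp_path):
        path = tmp_path / "ts.csv"
        pd.DataFrame({
            "treatment": ["methane"] * 3, "replicate": ["r1"] * 3,
            "day": [0, 15, 30], "value": [70.0, -1.0, 60.0],
            "unit": ["mM"] * 3}).to_csv(path, index=False)
        issues = validate_csv(path, "timeseries")
        assert len(issues) == 1
        assert issues[0].row == 1 and issues[0].column == "value"

    def test_unknown_unit_flagged(self, tmp_path):
        path = tmp_path / "ts.csv"
        pd.DataFrame({
            "treatment": ["methane"], "replicate": ["r1"], "day": [0],
            "value": [70.0], "unit": ["atm"]}).to_csv(path, index=False)
        issues = validate_csv(path, "timeseries")
        assert any(i.column == "unit" for i in issues)

    def test_duplicate_keys_rejected(self, tmp_path):
        path = tmp_path / "ts.csv"
        pd.DataFrame({
            "treatment": ["methane"] * 2, "replicate": ["r1"] * 2,
            "day": [0, 0], "value": [70.0, 71.0], "unit": ["mM"] * 2
        }).to_csv(path, index=False)
        issues = validate_csv(path, "timeseries")
        assert len(issues) == 2  # both rows named

    def test_missing_columns_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1]}).to_csv(path, index=False)
        issues = validate_csv(path, "assays")
        assert "missing columns" in issues[0].message


class TestPipeline:
    def test_full_pipeline_writes_report_bundle(self, tmp_path, noiseless_dataset):
        inputs = dataset_to_csvs(noiseless_dataset, tmp_path / "in")
        config = RunConfig(
            timeseries_csv=inputs["timeseries"], assays_csv=inputs["assays"],
            isotopes_csv=inputs["isotopes"], output_dir=tmp_path / "out")
        paths = run_pipeline(config)
        for key in ("rates", "srr", "table4", "transfers", "report"):
            assert paths[key].exists()
        table4 = pd.read_csv(paths["table4"])
        assert len(table4) == 4
        assert "observed_ratio_corrected" in table4.columns

    def test_rerun_is_byte_identical(self, tmp_path, noiseless_dataset):
        inputs = dataset_to_csvs(noiseless_dataset, tmp_path / "in")
        outs = []
        for run in ("a", "b"):
            config = RunConfig(timeseries_csv=inputs["timeseries"],
                               assays_csv=inputs["assays"],
                               output_dir=tmp_path / run)
            outs.append(run_pipeline(config))
        assert outs[0]["table4"].read_bytes() == outs[1]["table4"].read_bytes()

    def test_missing_input_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            RunConfig(timeseries_csv=tmp_path / "nope.csv",
                      assays_csv=tmp_path / "nope2.csv")

    def test_schema_violation_halts_pipeline(self, tmp_path, noiseless_dataset):
        inputs = dataset_to_csvs(noiseless_dataset, tmp_path / "in")
        bad = pd.read_csv(inputs["timeseries"])
        bad.loc[0, "unit"] = "psi"
        bad.to_csv(inputs["timeseries"], index=False)
        config = RunConfig(timeseries_csv=inputs["timeseries"],
                           assays_csv=inputs["assays"],
                           output_dir=tmp_path / "out")
        with pytest.raises(ValueError, match="validation"):
            run_pipeline(config)


class TestCli:
    def test_simulate_then_report_workflow(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        result = runner.invoke(cli_main, ["simulate", "--seed", "4",
                                          "--out", str(sim_dir)])
        assert result.exit_code == 0, result.output
        out_dir = tmp_path / "report"
        result = runner.invoke(cli_main, [
            "report", "--timeseries", str(sim_dir / "timeseries.csv"),
            "--assays", str(sim_dir / "assays.csv"),
            "--isotopes", str(sim_dir / "isotopes.csv"),
            "--outdir", str(out_dir)])
        assert result.exit_code == 0, result.output
        assert (out_dir / "table4.csv").exists()
        assert "Coupling ledger" in (out_dir / "report.txt").read_text()

    def test_stoich_subcommand_prints_reactions(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["stoich", "--source", "derived",
                                          "--alkane", "ethane"])
        assert result.exit_code == 0, result.output
        assert "7/4" in result.output and "balanced: True" in result.output

    def test_rates_subcommand(self, tmp_path, noiseless_dataset):
        paths = dataset_to_csvs(noiseless_dataset, tmp_path)
        runner = CliRunner()
        out = tmp_path / "rates.csv"
        result = runner.invoke(cli_main, ["rates", "--timeseries",
                                          str(paths["timeseries"]),
                                          "--out", str(out)])
        assert result.exit_code == 0, result.output
        df = pd.read_csv(out)
        row = df[df["treatment"] == "propane"].iloc[0]
        assert row["rate_nmol_per_ml_day"] == pytest.approx(354.0, abs=1e-6)
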