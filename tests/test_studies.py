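"""Study-record IO, replication reports, generators, and the CLI surface."""

import json
import math

import numpy as np
import pytest
from click.testing import CliRunner

from repbf import (
    BinomialCount,
    CrossTable,
    ReportConfig,
    StudyRecord,
    TStatSummary,
    TwoSampleSummary,
    chain_evidence,
    generate_binomial_series,
    generate_ttest_series,
    pool_two_sample_summaries,
    read_studies,
    render_report_text,
    report_to_json,
    run_replication_report,
    t_from_summaries,
    write_studies,
)
from repbf.cli import main as cli_main


@pytest.fixture
def krupenye_records():
    return [
        StudyRecord("binomial", "original", BinomialCount(20, 30), "experiment 1"),
        StudyRecord("binomial", "replication", BinomialCount(17, 22), "experiment 2"),
    ]


@pytest.fixture
def golf_records():
    return [
        StudyRecord("ttest", "original", TStatSummary(2.14, 14, 14), "superstition"),
        StudyRecord("ttest", "replication", TStatSummary(0.29, 58, 66), "direct replication"),
        StudyRecord("ttest", "combined", TStatSummary(1.14, 72, 80), "pooled"),
    ]


@pytest.fixture
def endowment_records():
    t1 = CrossTable(((15, 12), (8, 21)), row_labels=("Flowers", "Birds"),
                    col_labels=("Fewer flowers", "Fewer birds"))
    t2 = CrossTable(((11, 16), (14, 10)), row_labels=("Flowers", "Birds"),
                    col_labels=("Fewer flowers", "Fewer birds"))
    return [
        StudyRecord("contingency", "original", t1, "original"),
        StudyRecord("contingency", "replication", t2, "replication"),
    ]


class TestReadWriteStudies:
    def test_json_round_trip_all_designs(self, tmp_path, krupenye_records,
                                         golf_records, endowment_records):
        for records in (krupenye_records, golf_records, endowment_records):
            path = tmp_path / "studies.json"
            write_studies(records, path)
            back = read_studies(path)
            assert back == records

    def test_csv_round_trip_binomial(self, tmp_path, krupenye_records):
        path = tmp_path / "studies.csv"
        write_studies(krupenye_records, path)
        assert read_studies(path) == krupenye_records

    def test_csv_contingency_tables_pool_correctly(self, tmp_path):
        path = tmp_path / "tables.csv"
        path.write_text(
            "design,role,label,c11,c12,c21,c22\n"
            "contingency,original,original,15,12,8,21\n"
            "contingency,replication,replication,11,16,14,10\n"
        )
        records = read_studies(path)
        assert len(records) == 2
        from repbf import pool_tables

        pooled = pool_tables(records[0].payload, records[1].payload)
        assert pooled.counts == ((26, 28), (22, 31))

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_studies(path)
        path.write_text("[]")
        with pytest.raises(ValueError, match="no study records"):
            read_studies(path)

    def test_malformed_record_reports_index(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps([
            {"design": "binomial", "successes": 3, "trials": 10},
            {"design": "binomial", "successes": 12, "trials": 10},
        ]))
        with pytest.raises(ValueError, match="record 1"):
            read_studies(path)


class TestReplicationReport:
    def test_binomial_report_reproduces_published_chain(self, krupenye_records):
        rep = run_replication_report(krupenye_records)
        assert round(rep["complete"]["bf10"], 3) == 18.961
        assert round(rep["replication"]["bf10"], 3) == 16.448
        ci = rep["studies"][0]["credible_interval"]
        assert (round(ci["lower"], 3), round(ci["upper"], 3)) == (0.486, 0.808)
        assert abs(rep["parity"]["p_value"] - 0.098) < 0.005

    def test_ttest_report_reproduces_published_chain(self, golf_records):
        rep = run_replication_report(golf_records)
        assert round(rep["studies"][0]["bf10"], 3) == 1.820
        assert round(rep["complete"]["bf10"], 3) == 0.318
        assert abs(rep["replication"]["bf10"] - 0.175) < 0.005

    def test_ttest_summaries_pool_without_combined_record(self):
        records = [
            StudyRecord("ttest", "original", TwoSampleSummary(14, 1.0, 1.0, 14, 0.2, 1.1)),
            StudyRecord("ttest", "replication", TwoSampleSummary(30, 0.5, 1.0, 30, 0.4, 0.9)),
        ]
        rep = run_replication_report(records)
        pooled = pool_two_sample_summaries(records[0].payload, records[1].payload)
        assert rep["pooled_t"]["t"] == pytest.approx(t_from_summaries(pooled).t)

    def test_tstat_payloads_without_combined_record_fail_loudly(self, golf_records):
        with pytest.raises(ValueError, match="combined"):
            run_replication_report(golf_records[:2])

    def test_contingency_report_reproduces_published_chain(self, endowment_records):
        rep = run_replication_report(endowment_records)
        assert round(rep["studies"][0]["bf10"], 3) == 2.880
        assert round(rep["complete"]["bf10"], 3) == 0.298
        assert abs(rep["replication"]["bf10"] - 0.103) < 0.005
        assert abs(rep["studies"][0]["chi_square"]["statistic"] - 4.51) < 0.01

    def test_single_original_study_has_no_replication_section(self):
        rep = run_replication_report(
            [StudyRecord("binomial", "original", BinomialCount(20, 30))]
        )
        assert rep["replication"] is None
        assert "single original" in rep["note"]

    def test_order_restricted_policy_smaller_for_opposing_replication(self):
        records = [
            StudyRecord("binomial", "original", BinomialCount(20, 30)),
            StudyRecord("binomial", "replication", BinomialCount(2, 22)),
        ]
        rep = run_replication_report(
            records, ReportConfig(direction_policy="order_restricted_by_original")
        )
        assert rep["replication"]["direction"] == "greater"
        assert rep["replication"]["bf10_order_restricted"] < rep["replication"]["bf10"]

    def test_order_restricted_policy_for_ttest(self, golf_records):
        rep = run_replication_report(
            golf_records, ReportConfig(direction_policy="order_restricted_by_original")
        )
        assert rep["replication"]["direction"] == "positive"
        assert rep["replication"]["bf10_order_restricted"] > 0

    def test_mixed_designs_rejected(self, krupenye_records, endowment_records):
        with pytest.raises(ValueError, match="mixed"):
            run_replication_report(krupenye_records + endowment_records)

    def test_text_and_json_agree_at_rounding(self, krupenye_records):
        rep = run_replication_report(krupenye_records)
        text = render_report_text(rep, rounding=3)
        rounded = json.loads(report_to_json(rep, rounding=3))
        assert str(rounded["complete"]["bf10"]) in text
        assert str(rounded["replication"]["bf10"]) in text


class TestGenerators:
    def test_determinism(self):
        a = generate_binomial_series(0.6, 25, 4, seed=42)
        b = generate_binomial_series(0.6, 25, 4, seed=42)
        assert a == b
        c = generate_ttest_series(0.5, 12, 3, seed=42)
        d = generate_ttest_series(0.5, 12, 3, seed=42)
        assert c == d
        assert generate_binomial_series(0.6, 25, 4, seed=43) != a

    def test_reports_are_byte_identical_for_same_seed(self):
        reps = [
            report_to_json(run_replication_report(generate_binomial_series(0.6, 40, 3, seed=9)))
            for _ in range(2)
        ]
        assert reps[0] == reps[1]

    def test_certain_success(self):
        for rec in generate_binomial_series(1.0, 10, 3, seed=0):
            assert rec.payload.successes == rec.payload.trials

    def test_chain_identity_on_generated_series(self):
        records = generate_binomial_series(0.35, 50, 5, seed=123)
        chain = chain_evidence([r.payload for r in records], "binomial")
        assert math.log(chain.chain_product) == pytest.approx(
            chain.complete_bf.log_bf10, abs=1e-10
        )

    def test_null_series_accumulates_null_evidence(self):
        """Under a true null, the median complete BF01 across seeds exceeds 1."""
        bf01s = []
        for seed in range(60):
            records = generate_binomial_series(0.5, 100, 5, seed=seed)
            chain = chain_evidence([r.payload for r in records], "binomial")
            bf01s.append(chain.complete_bf.bf01)
        assert np.median(bf01s) > 1.0

    def test_zero_effect_gives_centered_pooled_t(self):
        ts = []
        for seed in range(300):
            records = generate_ttest_series(0.0, 10, 2, seed=seed)
            pooled = pool_two_sample_summaries(records[0].payload, records[1].payload)
            ts.append(t_from_summaries(pooled).t)
        assert abs(np.mean(ts)) < 3 / math.sqrt(len(ts))  # ~3 SEs of a unit-sd mean

    def test_nuisance_shifts_degrade_pooled_evidence(self):
        """Large per-study location shifts inflate the pooled variance and
        weaken the pooled-data evidence for a real effect."""
        log_bfs = {0.0: [], 5.0: []}
        for shift_sd in log_bfs:
            for seed in range(40):
                records = generate_ttest_series(0.8, 20, 2, seed=seed, shift_sd=shift_sd)
                chain = chain_evidence([r.payload for r in records], "ttest")
                log_bfs[shift_sd].append(chain.complete_bf.log_bf10)
        assert np.mean(log_bfs[5.0]) < np.mean(log_bfs[0.0])

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_binomial_series(1.5, 10, 2, seed=0)
        with pytest.raises(ValueError):
            generate_ttest_series(0.5, 1, 2, seed=0)


class TestCLI:
    def test_binom_subcommand(self):
        result = CliRunner().invoke(cli_main, ["binom", "20/30"])
        assert result.exit_code == 0
        assert "BF10 = 1.153" in result.output
        assert "(0.486, 0.808)" in result.output

    def test_ttest_subcommand(self):
        result = CliRunner().invoke(cli_main, ["ttest", "--t", "2.14", "--n1", "14", "--n2", "14"])
        assert result.exit_code == 0
        assert "BF10 = 1.82" in result.output

    def test_table_subcommand(self):
        result = CliRunner().invoke(cli_main, ["table", "15,12;8,21"])
        assert result.exit_code == 0
        assert "BF10 = 2.88" in result.output

    def test_simulate_then_report(self, tmp_path):
        path = str(tmp_path / "sim.json")
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["simulate", "--design", "binomial", "--truth", "0.7",
             "--n", "30", "--k", "2", "--seed", "5", "--out", path],
        )
        assert result.exit_code == 0
        out_json = str(tmp_path / "report.json")
        result = runner.invoke(cli_main, ["report", path, "--json-out", out_json])
        assert result.exit_code == 0
        assert "replication BF10" in result.output
        rep = json.loads((tmp_path / "report.json").read_text())
        assert rep["design"] == "binomial"
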