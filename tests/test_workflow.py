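"""Target-list parsing, end-to-end analysis, idempotence and the CLI."""

import hashlib

import pandas as pd
import pytest
from click.testing import CliRunner

from ozid.cli import main as cli_main
from ozid.config import AnalysisConfig, load_config
from ozid.rawdata import write_run_store
from ozid.simulate import SimulatedLipid, SimulationSpec
from ozid.workflow import parse_target_list, run_workflow

from conftest import make_target


@pytest.fixture
def targets_csv(tmp_path):
    p = tmp_path / "targets.csv"
    p.write_text(
        "lipid,adduct,retention_time_min,extra\n"
        "PC(16:0/18:1),[M+H]+,5.0,x\n"
        "D5-PG(17:0/20:3),[M-H]-,8.0,y\n"
        "PE(16:0/18:1),[M-H]-,6.5,z\n"
    )
    return p


class TestTargetList:
    def test_valid_rows_parsed_ignoring_unknown_columns(self, targets_csv):
        targets, rejects = parse_target_list(targets_csv)
        assert len(targets) == 3 and rejects.empty
        assert targets[1].species.deuterium_label == 5

    def test_bad_lipid_name_becomes_reject(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "lipid,adduct,retention_time_min\n"
            "PC(16:0/18:1),[M+H]+,5.0\n"
            "ZZ(16:0),[M+H]+,6.0\n"
            "PC(16:0/18:1),[M+Zq]+,6.0\n"
        )
        targets, rejects = parse_target_list(p)
        assert len(targets) == 1 and len(rejects) == 2
        assert "ZZ" in rejects["reason"].iloc[0]

    def test_duplicates_deduplicated_with_warning(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "lipid,adduct,retention_time_min\n"
            "PC(16:0/18:1),[M+H]+,5.0\n"
            "PC(16:0/18:1),[M+H]+,5.0\n"
        )
        with pytest.warns(UserWarning, match="duplicate"):
            targets, _ = parse_target_list(p)
        assert len(targets) == 1

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("lipid,rt\nPC(16:0/18:1),5\n")
        with pytest.raises(ValueError, match="retention_time_min"):
            parse_target_list(p)

    def test_tsv_accepted(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("lipid\tadduct\tretention_time_min\nPC(16:0/18:1)\t[M+H]+\t5.0\n")
        targets, _ = parse_target_list(p)
        assert len(targets) == 1


class TestEndToEnd:
    def test_clean_run_accepts_exactly_planted_sites(self, pg_standard_run):
        run, truth, target = pg_standard_run
        res = run_workflow([target], run)
        acc = res.results[res.results["decision"] == "accepted"]
        assert set(zip(acc["index"], acc["n_position"])) == {(1, 6), (2, 9), (3, 12)}
        assert len(res.results) == len(truth)

    def test_absent_target_skipped_with_reason(self, pg_standard_run):
        run, _, target = pg_standard_run
        ghost = make_target("PC(16:0/18:1)", "[M+H]+", 8.0)
        res = run_workflow([ghost, target], run)
        skipped = [d for d in res.diagnostics if d.status == "skipped"]
        assert len(skipped) == 1
        assert skipped[0].reason == "precursor not detected"
        # the other target is still fully analyzed
        assert (res.results["decision"] == "accepted").sum() == 3

    def test_poisoned_target_cannot_change_others(self, pg_standard_run):
        run, _, target = pg_standard_run
        alone = run_workflow([target], run).results
        ghost = make_target("SM(d18:1/24:1)", "[M+H]+", 2.0)
        both = run_workflow([ghost, target], run).results
        pd.testing.assert_frame_equal(alone, both)

    def test_idempotent_results_csv(self, pg_standard_run, tmp_path):
        run, _, target = pg_standard_run
        hashes = []
        for name in ("a.csv", "b.csv"):
            res = run_workflow([target], run)
            p = tmp_path / name
            res.results.to_csv(p, index=False, float_format="%.6f")
            hashes.append(hashlib.sha256(p.read_bytes()).hexdigest())
        assert hashes[0] == hashes[1]

    def test_precursor_isotope_validation_rejects_wrong_species(self, pg_standard_run):
        run, _, _ = pg_standard_run
        # a lipid whose m/z happens to catch signal but with the wrong formula
        # is skipped by isotope validation rather than analyzed
        wrong = make_target("PG(17:0/20:3)", "[M-H]-", 8.0)  # unlabeled twin, -5 Da
        res = run_workflow([wrong], run)
        assert res.diagnostics[0].status == "skipped"

    def test_unknown_mode_rejected(self, pg_standard_run):
        run, _, target = pg_standard_run
        with pytest.raises(ValueError):
            run_workflow([target], run, mode="quantum")

    def test_dl_mode_requires_model(self, pg_standard_run):
        run, _, target = pg_standard_run
        with pytest.raises(ValueError):
            run_workflow([target], run, mode="dl")


class TestConfig:
    def test_defaults_and_file_override(self, tmp_path):
        p = tmp_path / "c.cfg"
        p.write_text("mz_tol_xic = 0.01\nscore_cutoff = 0.2  # tighter\n")
        cfg = load_config(p)
        assert cfg.mz_tol_xic == 0.01 and cfg.score_cutoff == 0.2
        assert cfg.saturation_threshold == 1e6  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "c.cfg"
        p.write_text("mz_tolerance = 0.01\n")
        with pytest.raises(ValueError, match="unknown config key"):
            load_config(p)

    def test_precursor_cutoff_falls_back_to_score_cutoff(self):
        assert AnalysisConfig().effective_precursor_cutoff == 0.25
        assert AnalysisConfig(precursor_cutoff=0.1).effective_precursor_cutoff == 0.1


class TestCli:
    def test_no_args_usage_exit_2(self):
        result = CliRunner().invoke(cli_main, ["analyze"])
        assert result.exit_code == 2

    def test_fragments_tsv_on_stdout(self):
        result = CliRunner().invoke(cli_main, ["fragments", "PC(16:0/18:1)", "--adduct", "[M+H]+"])
        assert result.exit_code == 0
        lines = [l for l in result.output.splitlines() if l and not l.startswith("#")]
        assert lines[0].startswith("chain\tindex\tn_position")
        assert len(lines) == 1 + 15

    def test_analyze_writes_results(self, pg_standard_run, tmp_path, targets_csv):
        run, _, _ = pg_standard_run
        run_path = tmp_path / "run.h5"
        write_run_store(run, run_path)
        out = tmp_path / "out"
        result = CliRunner().invoke(
            cli_main,
            ["analyze", "-t", str(targets_csv), "-r", str(run_path), "-o", str(out)],
        )
        assert result.exit_code == 0, result.output
        df = pd.read_csv(out / "results.csv")
        assert (df["decision"] == "accepted").sum() == 3
        assert (out / "rejects.csv").exists()

    def test_simulate_command(self, tmp_path):
        lip = SimulatedLipid("PC(16:0/18:1)", "[M+H]+", 5.0, 1e5, {1: (9,)})
        spec = SimulationSpec(lipids=(lip,), rt_start=2.0, rt_end=8.0, seed=1)
        spec_path = tmp_path / "spec.json"
        spec.to_json(spec_path)
        out = tmp_path / "run.h5"
        result = CliRunner().invoke(
            cli_main,
            ["simulate", "--spec", str(spec_path), "-o", str(out), "--truth", str(tmp_path / "t.csv")],
        )
        assert result.exit_code == 0, result.output
        assert out.exists() and (tmp_path / "t.csv").exists()
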