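"""Campaign orchestration, config/IO round-trips and the CLI surface."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from nicheval.campaign import (
    CampaignConfig,
    load_config,
    run_campaign,
    save_config,
    stage_seed,
)
from nicheval.cli import main as cli_main
from nicheval.elicitation import pairs_from_matrix, published_confusion_matrix
from nicheval import io as nio
from nicheval.synthetic import default_space, make_bimodal


@pytest.fixture()
def small_config(tmp_path):
    # desk-scale campaign: two archetypes, reduced plot count and reps
    return CampaignConfig(
        n_plots=1500,
        seed=5,
        species=("rare_unimodal", "bimodal_mire"),
        methods=("GLM", "MARS"),
        prevalence={"rare_unimodal": 0.06, "bimodal_mire": 0.05},
        n_points_1d=25,
        n_grid_2d=12,
        auc_reps=2,
        out_dir=str(tmp_path / "campaign"),
    )


def _table1_scores(tmp_path):
    """Score CSV reconstructed from the packaged dual-assessment matrix."""
    pairs = pairs_from_matrix(published_confusion_matrix())
    rows = []
    for i, (ca, cb) in enumerate(pairs.itertuples(index=False)):
        sp, ax = f"s{i // 7}", f"axis{i % 7}"
        rows.append((sp, ax, "E1", ca))
        rows.append((sp, ax, "E2", cb))
    path = tmp_path / "scores.csv"
    pd.DataFrame(rows, columns=["species", "axis", "expert", "category"]
                 ).to_csv(path, index=False)
    return path


class TestStageSeed:
    def test_deterministic_and_distinct(self):
        assert stage_seed(1, "fit", "a") == stage_seed(1, "fit", "a")
        assert stage_seed(1, "fit", "a") != stage_seed(1, "fit", "b")
        assert stage_seed(1, "fit", "a") != stage_seed(2, "fit", "a")
        assert 0 <= stage_seed(3, "auc") < 2**31


class TestConfigRoundTrip:
    def test_save_load_identity(self, tmp_path):
        cfg = CampaignConfig(n_plots=777, seed=9, auc_reps=3,
                             prevalence={"rare_unimodal": 0.04})
        save_config(cfg, tmp_path / "c.kv")
        assert load_config(tmp_path / "c.kv") == cfg

    def test_malformed_line_cites_location(self, tmp_path):
        p = tmp_path / "c.kv"
        p.write_text("n_plots = 10\njunk line\n")
        with pytest.raises(ValueError, match="line 2"):
            load_config(p)


class TestIoRoundTrips:
    def test_species_truth_round_trip(self, tmp_path):
        sp = make_bimodal(default_space())
        nio.save_species(sp, tmp_path / "sp.kv")
        back = nio.load_species(tmp_path / "sp.kv")
        assert back.name == sp.name
        assert back.max_probability == pytest.approx(sp.max_probability)
        for a, b in zip(back.components, sp.components):
            assert a.optima == pytest.approx(b.optima)
            assert a.weight == pytest.approx(b.weight)

    def test_scores_round_trip_from_published_pairs(self, tmp_path):
        path = _table1_scores(tmp_path)
        scores = nio.load_scores(path)
        nio.save_scores(scores, tmp_path / "again.csv")
        pd.testing.assert_frame_equal(nio.load_scores(tmp_path / "again.csv"),
                                      scores)

    def test_unknown_category_rejected_with_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("species,axis,expert,category\ns1,ph,E1,amazing\n")
        with pytest.raises(ValueError, match="amazing"):
            nio.load_scores(p)

    def test_empty_score_file_is_empty_table(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        assert nio.load_scores(p).empty

    def test_non_binary_presence_rejected(self, tmp_path):
        space = default_space()
        p = tmp_path / "plots.csv"
        cols = ",".join(["plot_id", *space.names, "sp_x"])
        p.write_text(f"{cols}\n1,600,5,5,3,5,5,5,2\n")
        with pytest.raises(ValueError, match="sp_x"):
            nio.load_plots(p, space)


class TestRunCampaign:
    def test_cardinality_and_determinism(self, small_config, tmp_path):
        report = run_campaign(small_config)
        n_sp = len(small_config.species)
        assert report["stages"]["curves"]["n_curves"] == n_sp * 7
        assert report["stages"]["surfaces"]["n_surfaces"] == n_sp
        assert report["stages"]["auc"]["n_results"] == n_sp * 2
        out = tmp_path / "campaign"
        first = {f.name: f.read_bytes()
                 for f in out.glob("*.csv")}
        # rerun into a fresh directory: byte-identical CSV artefacts
        small_config.out_dir = str(tmp_path / "campaign2")
        run_campaign(small_config)
        for name, blob in first.items():
            assert (tmp_path / "campaign2" / name).read_bytes() == blob

    def test_agreement_stage_reproduces_published_statistics(
            self, small_config, tmp_path):
        small_config.scores_csv = str(_table1_scores(tmp_path))
        report = run_campaign(small_config)
        ag = report["stages"]["agreement"]
        assert ag["grand_total"] == 290
        assert ag["identical"] == 126
        assert ag["overall_pct_display"] == 43
        assert ag["per_category_pct_display"] == {
            "excellent": 8, "good": 17, "moderate": 25, "poor": 40}


class TestCli:
    def test_version_and_help(self):
        runner = CliRunner()
        assert "nicheval" in runner.invoke(cli_main, ["--version"]).output
        res = runner.invoke(cli_main, ["--help"])
        for sub in ("simulate", "fit", "curves", "surface", "auc",
                    "allocate", "agree", "campaign"):
            assert sub in res.output

    def test_agree_command_on_published_scores(self, tmp_path):
        path = _table1_scores(tmp_path)
        runner = CliRunner()
        res = runner.invoke(cli_main, ["agree", "--scores", str(path),
                                       "--experts", "E1,E2",
                                       "--report", str(tmp_path / "r.json")])
        assert res.exit_code == 0, res.output
        assert "43" in res.output
        payload = json.loads((tmp_path / "r.json").read_text())
        assert payload["overall_pct"] == pytest.approx(100 * 126 / 290)

    def test_simulate_then_fit_then_auc(self, tmp_path):
        runner = CliRunner()
        plots_csv = tmp_path / "plots.csv"
        res = runner.invoke(cli_main, [
            "simulate", "--seed", "5", "--n-plots", "1200",
            "--out", str(plots_csv)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, [
            "fit", "--plots", str(plots_csv), "--species", "rare_unimodal",
            "--methods", "GLM", "--seed", "3",
            "--out", str(tmp_path / "bundle")])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, [
            "curves", "--fit", str(tmp_path / "bundle"),
            "--axis", "substrate_ph", "--out", str(tmp_path / "c.csv")])
        assert res.exit_code == 0, res.output
        curve = pd.read_csv(tmp_path / "c.csv")
        assert curve["favorability"].between(0, 1).all()
        res = runner.invoke(cli_main, [
            "auc", "--plots", str(plots_csv), "--species", "rare_unimodal",
            "--methods", "GLM", "--reps", "2", "--seed", "4"])
        assert res.exit_code == 0, res.output
        assert "mean AUC" in res.output

    def test_allocate_command(self, tmp_path):
        species_file = tmp_path / "species.txt"
        species_file.write_text("\n".join(f"sp{i}" for i in range(881)))
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "allocate", "--species-file", str(species_file),
            "--experts", "E1,E2", "--seed", "2",
            "--out", str(tmp_path / "alloc.json")])
        assert res.exit_code == 0, res.output
        payload = json.loads((tmp_path / "alloc.json").read_text())
        assert len(payload["dual_set"]) == 45
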