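"""Model/Results API, end-to-end pipeline, result files, and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from episis import (
    EpisisModel,
    GenotypeMatrix,
    PhenotypeVector,
    RunConfig,
    Table2x2,
    continuity_correct,
    odds_ratio_stats,
    pair_counts,
    run_episis,
    write_results,
)
from episis.cli import main as cli_main
from episis.model import _p_full


def _planted_dataset(seed=0, n=400, L=12):
    """Cases enriched in cell (2,2) of the (1, L-2) SNP pair."""
    rng = np.random.default_rng(seed)
    G = rng.binomial(2, 0.45, size=(n, L)).astype(np.int8)
    status = np.array([1] * (n // 2) + [0] * (n // 2), dtype=np.int8)
    risk = rng.random(n // 2) < 0.55
    G[np.flatnonzero(status == 1)[risk], 1] = 2
    G[np.flatnonzero(status == 1)[risk], L - 2] = 2
    return GenotypeMatrix(G), PhenotypeVector(status)


class TestEpisisModel:
    def test_constructor_accepts_arrays(self):
        G = np.random.default_rng(0).integers(0, 3, size=(20, 4))
        y = np.array([1] * 10 + [0] * 10)
        m = EpisisModel(G, y, snp_ids=list("abcd"))
        assert m.n_samples == 20 and m.n_snps == 4
        assert m.data.snp_ids == list("abcd")

    def test_from_dataframe(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "phenotype": [1] * 8 + [0] * 8,
                "rs1": rng.integers(0, 3, 16),
                "rs2": rng.integers(0, 3, 16),
            }
        )
        m = EpisisModel.from_dataframe(df)
        assert m.data.snp_ids == ["rs1", "rs2"]
        np.testing.assert_array_equal(m.endog, df["phenotype"])

    def test_p_full_conventions(self):
        assert _p_full("cdc", 1000) == 9 * 1000 * 999 // 2 + 3000
        assert _p_full("adc", 1000) == 1000 * 999 // 2

    def test_method_and_explicit_strategy_are_exclusive(self, make_dataset):
        g, y = make_dataset()
        m = EpisisModel(g, y)
        with pytest.raises(ValueError):
            m.fit("lcdc", coding="cdc")
        with pytest.raises(ValueError, match="unknown method"):
            m.fit("boost")

    def test_gamma_validation(self, make_dataset):
        g, y = make_dataset()
        with pytest.raises(ValueError, match="gamma"):
            EpisisModel(g, y).fit("pcdc", gamma=1.5)


class TestEpisisResults:
    def test_planted_effect_selected_with_consistent_report(self):
        g, y = _planted_dataset()
        res = EpisisModel(g, y).fit("lcdc", d=64, gamma=(0.0, 0.5, 1.0))
        sel = res.selection(0.5)
        assert len(sel) >= 1
        top = sel.iloc[0]
        assert {top["snp1"], top["snp2"]} == {"SNP2", f"SNP{g.n_snps - 1}"}
        # every reported OR/CI must be recomputable from its 2x2 table
        for _, row in sel.iterrows():
            if row["kind"] != "pair_cell":
                continue
            i = g.snp_ids.index(row["snp1"])
            j = g.snp_ids.index(row["snp2"])
            pc = pair_counts(g, y, min(i, j), max(i, j))
            cell = int(row["cell_or_mask"])
            t = Table2x2(
                pc.case_counts[cell],
                pc.n_cases - pc.case_counts[cell],
                pc.control_counts[cell],
                pc.n_controls - pc.control_counts[cell],
            )
            or_, _, p, ci = odds_ratio_stats(continuity_correct(t))
            assert row["OR"] == pytest.approx(or_)
            assert row["p"] == pytest.approx(p)
            assert row["CI_low"] == pytest.approx(ci[0])
            assert row["CI_high"] == pytest.approx(ci[1])

    def test_lcdc_and_pcdc_agree_on_strong_top_pair(self):
        g, y = _planted_dataset(seed=3)
        pair = {"SNP2", f"SNP{g.n_snps - 1}"}
        for meth in ("lcdc", "pcdc"):
            res = EpisisModel(g, y).fit(meth, d=64, gamma=0.5)
            sel = res.selection(0.5)
            assert len(sel) >= 1
            assert {sel.iloc[0]["snp1"], sel.iloc[0]["snp2"]} == pair

    def test_dimension_monotone_and_summary_smoke(self):
        g, y = _planted_dataset(seed=4)
        gammas = tuple(np.round(np.arange(0, 1.01, 0.25), 10))
        res = EpisisModel(g, y).fit("padc", d=64, gamma=gammas)
        dims = [res.dimension(gv) for gv in gammas]
        assert all(a >= b for a, b in zip(dims, dims[1:]))
        text = res.summary()
        assert "EPISIS" in text and "gamma=0.5" in text

    def test_determinism_of_full_fit(self):
        g, y = _planted_dataset(seed=5)
        r1 = EpisisModel(g, y).fit("padc", d=32, gamma=0.6)
        r2 = EpisisModel(g, y).fit("padc", d=32, gamma=0.6)
        pd.testing.assert_frame_equal(r1.selection(), r2.selection())
        assert r1.run_metadata() == r2.run_metadata()


class TestPipeline:
    def test_run_episis_equals_stagewise_composition(self, tmp_path):
        g, y = _planted_dataset(seed=6, n=300, L=10)
        path = tmp_path / "toy.txt"
        rows = ["\t".join(map(str, [y.status[k], *g.genotypes[k]])) for k in
                range(g.n_samples)]
        path.write_text("\n".join(rows) + "\n")
        cfg = RunConfig(table=str(path), method="lcdc", d=32, gammas=(0.5,),
                        qc=None, out=None)
        res = run_episis(cfg)
        direct = EpisisModel(g, y).fit("lcdc", d=32, gamma=0.5)
        pd.testing.assert_frame_equal(res.selection(), direct.selection())

    def test_write_results_roundtrip_and_metadata(self, tmp_path):
        g, y = _planted_dataset(seed=7)
        res = EpisisModel(g, y).fit("lcdc", d=32, gamma=(0.5,))
        prefix = str(tmp_path / "run1")
        write_results(res, prefix, seed=123)
        frame = pd.read_csv(prefix + ".interactions.tsv", sep="\t")
        sel = res.selection()
        assert len(frame) == len(sel)
        assert list(frame["snp1"]) == list(sel["snp1"])
        np.testing.assert_allclose(frame["OR"], sel["OR"], rtol=1e-9)
        meta = json.load(open(prefix + ".meta.json"))
        assert meta["seed"] == 123
        assert meta["d"] == 32
        assert meta["p_full"] == _p_full("cdc", g.n_snps)
        assert meta["lambda2"] == pytest.approx(1.0 / g.n_samples)

    def test_empty_selection_writes_header_only(self, tmp_path):
        rng = np.random.default_rng(8)
        G = rng.binomial(2, 0.3, size=(200, 8)).astype(np.int8)
        y = PhenotypeVector(np.array([1] * 100 + [0] * 100))
        res = EpisisModel(GenotypeMatrix(G), y).fit("pcdc", d=16, gamma=1.0)
        prefix = str(tmp_path / "empty")
        write_results(res, prefix)
        lines = open(prefix + ".interactions.tsv").read().splitlines()
        assert len(lines) == 1 and lines[0].startswith("snp1\t")

    def test_byte_identical_reruns(self, tmp_path):
        g, y = _planted_dataset(seed=9)
        res = EpisisModel(g, y).fit("padc", d=32, gamma=(0.4, 0.8))
        p1, p2 = str(tmp_path / "a"), str(tmp_path / "b")
        write_results(res, p1, seed=5)
        write_results(res, p2, seed=5)
        assert open(p1 + ".interactions.tsv", "rb").read() == open(
            p2 + ".interactions.tsv", "rb"
        ).read()
        assert open(p1 + ".meta.json", "rb").read() == open(
            p2 + ".meta.json", "rb"
        ).read()


class TestCli:
    def _toy_table(self, tmp_path, seed=10):
        g, y = _planted_dataset(seed=seed, n=200, L=8)
        path = tmp_path / "toy.txt"
        rows = ["\t".join(map(str, [y.status[k], *g.genotypes[k]])) for k in
                range(g.n_samples)]
        path.write_text("\n".join(rows) + "\n")
        return path

    def test_table_run_writes_outputs(self, tmp_path):
        path = self._toy_table(tmp_path)
        out = str(tmp_path / "run1")
        result = CliRunner().invoke(
            cli_main,
            ["--table", str(path), "--method", "padc", "--gamma", "0.6",
             "--d", "32", "--no-qc", "--out", out],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "run1.interactions.tsv").exists()
        assert (tmp_path / "run1.meta.json").exists()

    def test_gamma_out_of_range_is_usage_error(self, tmp_path):
        path = self._toy_table(tmp_path)
        result = CliRunner().invoke(
            cli_main,
            ["--table", str(path), "--gamma", "1.5", "--out", str(tmp_path / "x")],
        )
        assert result.exit_code == 2

    def test_unknown_flag_is_usage_error(self, tmp_path):
        result = CliRunner().invoke(cli_main, ["--frobnicate"])
        assert result.exit_code == 2

    def test_missing_input_is_usage_error(self, tmp_path):
        result = CliRunner().invoke(cli_main, ["--out", str(tmp_path / "x")])
        assert result.exit_code == 2

    def test_identical_invocations_identical_files(self, tmp_path):
        path = self._toy_table(tmp_path)
        runner = CliRunner()
        outs = []
        for name in ("r1", "r2"):
            out = str(tmp_path / name)
            res = runner.invoke(
                cli_main,
                ["--table", str(path), "--method", "lcdc", "--gamma", "0.5",
                 "--d", "24", "--no-qc", "--out", out],
            )
            assert res.exit_code == 0, res.output
            outs.append(open(out + ".interactions.tsv", "rb").read())
        assert outs[0] == outs[1]

    def test_simulate_config_run(self, tmp_path):
        cfgfile = tmp_path / "sim.cfg"
        cfgfile.write_text(
            "n_snps = 20\nn_case = 50\nn_control = 50\nseed = 3\n"
        )
        out = str(tmp_path / "sim")
        result = CliRunner().invoke(
            cli_main,
            ["--simulate-config", str(cfgfile), "--method", "pcdc",
             "--gamma", "1.0", "--d", "16", "--no-qc", "--out", out],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "sim.interactions.tsv").exists()
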