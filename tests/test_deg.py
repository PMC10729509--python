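"""Differential-expression screen: statistics, thresholds, and edge cases."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from targetnet.deg import (
    ExpressionMatrix,
    collapse_duplicate_genes,
    flag_degs,
    read_series_matrix,
    screen_degs,
)
from targetnet.deg import test_two_groups as run_two_group_test
from targetnet.synthetic import simulate_expression


def _matrix(values, n_ctrl, n_case, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = [f"c{i}" for i in range(n_ctrl)] + [f"t{i}" for i in range(n_case)]
    groups = pd.Series(["control"] * n_ctrl + ["case"] * n_case, index=cols)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols), groups)


class TestExpressionMatrix:
    def test_rejects_small_groups_and_missing_labels(self):
        with pytest.raises(ValueError):
            _matrix(np.ones((3, 3)), 1, 2)
        df = pd.DataFrame(np.ones((2, 4)), index=["a", "b"], columns=list("wxyz"))
        with pytest.raises(ValueError):
            ExpressionMatrix(df, pd.Series({"w": "case", "x": "case", "y": "control"}))

    def test_collapse_keeps_highest_mean_row(self):
        df = pd.DataFrame(
            [[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]],
            index=["dup", "dup", "other"],
            columns=["s1", "s2"],
        )
        out = collapse_duplicate_genes(df)
        assert list(out.index) == ["dup", "other"]
        assert out.loc["dup", "s1"] == 5.0


class TestTwoGroupTests:
    def test_constant_gene_gives_null_result(self, caplog):
        vals = np.vstack([np.ones(8), np.random.default_rng(0).normal(size=8)])
        m = _matrix(vals, 4, 4)
        with caplog.at_level("WARNING"):
            res = run_two_group_test(m, method="welch")
        assert res.loc["g0", "log2fc"] == 0.0
        assert res.loc["g0", "p_value"] == 1.0
        assert not flag_degs(res).loc["g0", "passes"]

    @pytest.mark.parametrize("method", ["welch", "moderated"])
    def test_planted_effect_is_detected(self, method):
        m, truth = simulate_expression(200, 32, 20, 2.0, 0.5, seed=7)
        res = run_two_group_test(m, method=method)
        up, down = screen_degs(res, 1.0, 0.05)
        assert truth.de_genes <= (up | down)

    def test_welch_null_pvalues_are_uniform(self):
        m, _ = simulate_expression(10_000, 32, 0, 2.0, 1.0, seed=5)
        res = run_two_group_test(m, method="welch")
        stat = stats.kstest(res["p_value"], "uniform")
        assert stat.pvalue > 0.01

    def test_moderated_approaches_welch_with_sample_size(self):
        gaps = []
        for n in (4, 16, 64):
            m, _ = simulate_expression(400, n, 40, 2.0, 0.8, seed=13)
            pw = run_two_group_test(m, "welch")["p_value"]
            pm = run_two_group_test(m, "moderated")["p_value"]
            gaps.append(float((pw - pm).abs().max()))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.15

    def test_moderated_matches_limma_oracle(self, tmp_path):
        """Dual-route check: the moments-based variance shrinkage must agree
        with the reference empirical-Bayes implementation in R."""
        rng = np.random.default_rng(11)
        n_genes, n = 300, 5
        sig2 = 6.0 * 0.5 / rng.chisquare(6.0, n_genes)  # heteroscedastic genes
        base = rng.uniform(4, 12, n_genes)
        eff = np.where(rng.random(n_genes) < 0.1, 2.0, 0.0)
        x = np.empty((n_genes, 2 * n))
        for i in range(n_genes):
            x[i, :n] = base[i] + rng.normal(0, np.sqrt(sig2[i]), n)
            x[i, n:] = base[i] + eff[i] + rng.normal(0, np.sqrt(sig2[i]), n)
        m = _matrix(x, n, n)
        m.data.to_csv(tmp_path / "expr.tsv", sep="\t")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{tmp_path}/expr.tsv", row.names=1))
            group <- factor(c(rep("control",{n}), rep("case",{n})),
                            levels=c("control","case"))
            fit <- eBayes(lmFit(x, model.matrix(~group)))
            tt <- topTable(fit, coef=2, number=Inf, sort.by="none")
            write.table(data.frame(gene=rownames(tt), p=tt$P.Value),
                        "{tmp_path}/r.tsv", sep="\t", row.names=FALSE, quote=FALSE)
            """
        )
        (tmp_path / "check.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "check.R")], check=True, capture_output=True
        )
        r = pd.read_csv(tmp_path / "r.tsv", sep="\t", index_col=0)
        py = run_two_group_test(m, "moderated")
        dlog = np.abs(np.log10(py["p_value"].to_numpy()) - np.log10(r["p"].to_numpy()))
        assert dlog.max() < 1e-8


class TestScreen:
    def test_boundary_fold_change_is_excluded(self):
        res = pd.DataFrame(
            {"log2fc": [1.0, -1.5, 1.2], "t_stat": [5, -8, 6],
             "p_value": [0.001, 0.001, 0.05]},
            index=["exact", "dn", "pboundary"],
        )
        up, down = screen_degs(res, 1.0, 0.05)
        assert "exact" not in up | down  # |log2fc| must strictly exceed 1.0
        assert "pboundary" not in up | down  # p must be strictly below 0.05
        assert down == {"dn"}

    def test_up_down_partition(self):
        m, _ = simulate_expression(300, 16, 30, 2.5, 0.5, seed=3)
        up, down = screen_degs(run_two_group_test(m, "welch"))
        assert not up & down

    def test_row_order_invariance(self):
        m, _ = simulate_expression(100, 8, 10, 2.0, 0.5, seed=9)
        res = run_two_group_test(m, "welch")
        shuffled = res.sample(frac=1.0, random_state=0)
        assert screen_degs(res) == screen_degs(shuffled)

    def test_nonpositive_thresholds_rejected(self):
        res = pd.DataFrame({"log2fc": [2.0], "t_stat": [5.0], "p_value": [0.01]})
        with pytest.raises(ValueError):
            screen_degs(res, fc_threshold=0.0)
        with pytest.raises(ValueError):
            screen_degs(res, p_threshold=-0.1)


def test_series_matrix_reader(tmp_path):
    text = (
        "!Series_title\t\"demo\"\n"
        "!series_matrix_table_begin\n"
        '"ID_REF"\t"GSM1"\t"GSM2"\n'
        '"APOA1"\t7.1\t7.9\n'
        '"APOB"\t5.2\t5.0\n'
        "!series_matrix_table_end\n"
    )
    p = tmp_path / "series.txt"
    p.write_text(text)
    df = read_series_matrix(p)
    assert list(df.index) == ["APOA1", "APOB"]
    assert df.loc["APOA1", "GSM2"] == pytest.approx(7.9)
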