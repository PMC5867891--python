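"""FPKM, TMM, exact NB test, response classes, summaries, calibration."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from stresslnc.expression import (
    de_table,
    de_test,
    expressed_set,
    expression_summary,
    fpkm,
    nb_exact_pvalue,
    response_class,
    tmm_factors,
)
from stresslnc.models import CONDITIONS
from stresslnc.simulate import SimParams, assign_expression_truth, simulate_counts

from oracles import binomial_two_sided, tmm_factor_oracle


def _counts(rows, index=None):
    return pd.DataFrame(
        rows, index=index or [f"t{i}" for i in range(len(rows))], columns=list(CONDITIONS)
    )


class TestFpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"a": [10], "b": [0]}, index=["t1"]).T
        counts = pd.DataFrame([[10, 0]], index=["t1"], columns=["a", "b"]).T
        c = pd.DataFrame([[10], [0]], index=["t1", "t2"], columns=["x"])
        out = fpkm(c, pd.Series({"t1": 1000, "t2": 500}), pd.Series({"x": 1_000_000}))
        assert out.at["t1", "x"] == pytest.approx(10.0)
        assert out.at["t2", "x"] == 0.0

    def test_doubling_library_halves_fpkm(self):
        c = pd.DataFrame([[10]], index=["t"], columns=["x"])
        lens = pd.Series({"t": 1000})
        a = fpkm(c, lens, pd.Series({"x": 1e6})).iat[0, 0]
        b = fpkm(c, lens, pd.Series({"x": 2e6})).iat[0, 0]
        assert a == pytest.approx(2 * b)

    def test_zero_length_rejected(self):
        c = pd.DataFrame([[1]], index=["t"], columns=["x"])
        with pytest.raises(ValueError):
            fpkm(c, pd.Series({"t": 0}))


TOY_8x2 = pd.DataFrame(
    {
        "A": [120, 30, 512, 64, 1024, 77, 256, 331],
        "B": [100, 90, 480, 129, 2050, 69, 300, 333],
    },
    index=[f"g{i}" for i in range(8)],
)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        c = pd.DataFrame({"A": [10, 20, 30], "B": [10, 20, 30]})
        f = tmm_factors(c, ref_column="A")
        assert np.allclose(f.to_numpy(), 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        """Column B = 2 x A elementwise is a depth change, not a
        composition change: every M-value is 0 and both factors are 1."""
        a = np.array([11, 23, 47, 100, 217, 31, 64, 513])
        c = pd.DataFrame({"A": a, "B": 2 * a})
        f = tmm_factors(c, ref_column="A")
        assert np.allclose(f.to_numpy(), 1.0, atol=1e-12)

    def test_matches_spreadsheet_oracle_on_8x2_toy(self):
        f = tmm_factors(TOY_8x2, ref_column="A")
        raw = tmm_factor_oracle(TOY_8x2["B"], TOY_8x2["A"])
        want = np.array([1.0, raw])
        want = want / np.exp(np.mean(np.log(want)))
        assert np.allclose(f.to_numpy(), want, rtol=1e-10)

    def test_matches_edger_calcnormfactors(self, tmp_path):
        """Cross-check against the reference implementation in edgeR."""
        csv = tmp_path / "m.csv"
        TOY_8x2.to_csv(csv, index=False)
        script = tmp_path / "tmm.R"
        script.write_text(
            f"""suppressMessages(library(edgeR))
m <- as.matrix(read.csv("{csv}"))
f <- calcNormFactors(m, method="TMM", refColumn=1)
cat(sprintf("%.10f %.10f", f[1], f[2]))
"""
        )
        try:
            out = subprocess.run(
                ["Rscript", "--vanilla", str(script)],
                capture_output=True, text=True, timeout=120, check=True,
            ).stdout
        except (FileNotFoundError, subprocess.SubprocessError):
            pytest.skip("Rscript/edgeR unavailable")
        want = np.array([float(x) for x in out.split()])
        got = tmm_factors(TOY_8x2, ref_column="A").to_numpy()
        assert np.allclose(got, want, rtol=1e-6)

    def test_stable_under_scaling_one_library(self):
        """Scaling a whole library leaves every M-value unchanged, so the
        factors move only through the precision weights: they must stay
        within a few percent of the unscaled factors."""
        c = TOY_8x2.copy()
        f1 = tmm_factors(c, ref_column="A")
        c2 = c.copy()
        c2["B"] = c2["B"] * 4
        f2 = tmm_factors(c2, ref_column="A")
        assert np.allclose(f1.to_numpy(), f2.to_numpy(), atol=0.05)

    def test_all_zero_column_rejected(self):
        c = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(c)


class TestExactTest:
    def test_equal_counts_not_de(self):
        assert nb_exact_pvalue(50, 50, 0.1) == pytest.approx(1.0, abs=0.05)

    def test_dispersion_zero_equals_binomial_enumeration(self):
        """With dispersion 0 the conditional test is an exact binomial;
        p on counts (3, 30) equals full enumeration of all splits."""
        got = nb_exact_pvalue(3, 30, 0.0)
        want = binomial_two_sided(3, 30)
        assert got == pytest.approx(want, rel=1e-9)

    @pytest.mark.parametrize("pair", [(0, 12), (5, 9), (20, 41)])
    def test_binomial_agreement_more_pairs(self, pair):
        assert nb_exact_pvalue(*pair, 0.0) == pytest.approx(
            binomial_two_sided(*pair), rel=1e-9
        )

    def test_fold_cutoff_blocks_small_changes(self):
        """log2FC ~1.9 with a tiny p-value is still not DE under the
        4-fold rule."""
        rows = [[1000, 1000, 3730, 1000, 1000, 1000]]
        counts = _counts(rows)
        factors = pd.Series(1.0, index=CONDITIONS)
        lib = pd.Series(1e6, index=CONDITIONS)
        recs = de_test(counts, factors, 0.001, "leaf", "96h_vs_control",
                       library_sizes=lib)
        r = recs[0]
        assert abs(r.log2fc) < 2.0 and r.p_value < 1e-6
        assert r.is_de is False

    def test_label_swap_negates_log2fc_keeps_p(self):
        rows = [[30, 0, 300, 0, 0, 0]]
        counts = _counts(rows)
        swapped = counts.rename(
            columns={"leaf_control": "leaf_96h", "leaf_96h": "leaf_control"}
        )[list(CONDITIONS)]
        factors = pd.Series(1.0, index=CONDITIONS)
        lib = pd.Series(1e6, index=CONDITIONS)
        a = de_test(counts, factors, 0.1, "leaf", "96h_vs_control", library_sizes=lib)[0]
        b = de_test(swapped, factors, 0.1, "leaf", "96h_vs_control", library_sizes=lib)[0]
        assert a.log2fc == pytest.approx(-b.log2fc)
        assert a.p_value == pytest.approx(b.p_value)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_pvalue(1, 2, -0.5)


class TestResponseClass:
    @pytest.mark.parametrize(
        "de3,de96,expected",
        [
            (True, False, "early"),
            (False, True, "late"),
            (True, True, "prolonged"),
            (False, False, "none"),
        ],
    )
    def test_mapping(self, de3, de96, expected):
        assert response_class(de3, de96) == expected


class TestExpressedSet:
    def test_cutoff_boundary(self):
        f = pd.DataFrame([[1.0, 0.99, 0.0, 5.0, 1.0001, 0.5]], columns=list(CONDITIONS))
        e = expressed_set(f, 1.0)
        assert e.iloc[0].tolist() == [True, False, False, True, True, False]


class TestExpressionSummary:
    def test_constant_group(self):
        f = pd.DataFrame(
            np.full((4, 6), 8.0), index=list("abcd"), columns=list(CONDITIONS)
        )
        groups = pd.Series("g", index=list("abcd"))
        out = expression_summary(f, groups)
        assert out["median_log2_fpkm"].to_numpy() == pytest.approx(3.0)
        assert out["iqr_log2_fpkm"].to_numpy() == pytest.approx(0.0)

    def test_quartiles_match_sort_oracle(self, rng):
        vals = np.exp(rng.uniform(0, 5, size=(40, 6)))
        f = pd.DataFrame(vals, index=[f"t{i}" for i in range(40)], columns=list(CONDITIONS))
        groups = pd.Series("g", index=f.index)
        out = expression_summary(f, groups, cutoff=1.0).set_index("condition")
        for cond in CONDITIONS:
            v = np.log2(np.sort(vals[:, list(CONDITIONS).index(cond)]))
            v = v[np.sort(vals[:, list(CONDITIONS).index(cond)]) >= 1.0]
            assert out.at[cond, "median_log2_fpkm"] == pytest.approx(np.percentile(v, 50))

    def test_planted_high_expression_group_ranks_top(self, small_study, pipeline_result):
        """Summary medians are ordered consistently with the planted base
        means of the surviving groups."""
        out = pipeline_result["expression_summary"]
        assert {"coding"} <= set(out["group"])
        assert (out["n_expressed"] > 0).all()
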