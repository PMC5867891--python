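"""Trans-NAT discovery, pair classes, co-expression, expression ratios."""

import numpy as np
import pandas as pd
import pytest

from stresslnc.models import CONDITIONS, TransNATPair
from stresslnc.transnat import (
    classify_pair,
    classify_pairs,
    coexpression_categories,
    coexpression_table,
    expression_ratio,
    find_pairs,
    top_paired,
)

from oracles import longest_common_substring, revcomp, sw_local


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _pair(qcov, tcov, longest, qlen=200, tlen=200):
    return TransNATPair(
        query_id="q",
        target_id="t",
        target_type="coding",
        query_blocks=[(0, int(qcov * qlen))],
        target_blocks=[(0, int(tcov * tlen))],
        longest_run=longest,
        coverage_query=qcov,
        coverage_target=tcov,
    )


class TestFindPairs:
    def test_planted_revcomp_window_found_with_exact_block(self, rng):
        coding = _rand(rng, 600)
        window = coding[200:350]  # 150 nt
        lnc = _rand(rng, 100) + revcomp(window) + _rand(rng, 150)
        pairs = find_pairs([("L", lnc)], [("C", coding)], min_align_len=50)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.longest_run == 150
        assert p.query_blocks == [(100, 250)]
        assert p.target_blocks == [(200, 350)]

    def test_block_coordinates_match_dp_oracle(self, rng):
        """Pairing block equals the longest exact common substring (full
        dynamic program) of the lncRNA vs the reverse-complemented
        target."""
        coding = _rand(rng, 300)
        window = coding[40:180]
        lnc = _rand(rng, 60) + revcomp(window) + _rand(rng, 80)
        pairs = find_pairs([("L", lnc)], [("C", coding)], min_align_len=50)
        ln, qs, _ = longest_common_substring(lnc, revcomp(coding))
        assert pairs[0].query_blocks[0] == (qs, qs + ln)

    def test_unrelated_sequences_produce_no_long_pairing(self, rng):
        """Random 500-mers share no >=50 nt complementary run (max random
        run is ~<20 nt), over many seed pairs."""
        for _ in range(50):
            a, b = _rand(rng, 500), _rand(rng, 500)
            assert find_pairs([("a", a)], [("b", b)], min_align_len=50) == []

    def test_self_pairs_excluded(self, rng):
        lnc = _rand(rng, 300)
        assert find_pairs([("a", lnc)], [], min_align_len=50) == []

    def test_lnc_lnc_pair_reported_once(self, rng):
        a = _rand(rng, 400)
        b = _rand(rng, 100) + revcomp(a[100:260]) + _rand(rng, 120)
        pairs = find_pairs([("a", a), ("b", b)], [], min_align_len=50)
        assert len(pairs) == 1
        assert pairs[0].target_type == "lncRNA"


class TestClassifyPair:
    def test_high_coverage_when_both_above_half(self):
        # 180 paired nt on lengths (200, 300)
        p = _pair(180 / 200, 180 / 300, 180)
        assert classify_pair(p) == "high_coverage"

    def test_nt100_when_coverage_low_but_run_long(self):
        # 150 paired nt on lengths (200, 400): 0.75 / 0.375
        p = _pair(150 / 200, 150 / 400, 150)
        assert classify_pair(p) == "nt100"

    def test_run_of_exactly_100_is_not_a_pair(self):
        p = _pair(0.3, 0.2, 100)
        assert classify_pair(p) is None
        assert classify_pair(_pair(0.3, 0.2, 101)) == "nt100"

    def test_either_member_mode(self):
        p = _pair(0.8, 0.3, 90)
        assert classify_pair(p, both_members=True) is None
        assert classify_pair(p, both_members=False) == "high_coverage"

    def test_symmetric_under_member_swap(self):
        p = _pair(0.8, 0.6, 120)
        q = _pair(0.6, 0.8, 120)
        assert classify_pair(p) == classify_pair(q)


class TestCoexpression:
    def _expressed(self):
        return pd.DataFrame(
            {
                "leaf_control": [True, True],
                "leaf_3h": [True, False],
                "leaf_96h": [False, True],
                "root_control": [False, False],
                "root_3h": [True, True],
                "root_96h": [False, False],
            },
            index=["L", "C"],
        )

    def test_categories_per_condition(self):
        p = _pair(0.9, 0.9, 150)
        p.query_id, p.target_id, p.pair_class = "L", "C", "nt100"
        cats = coexpression_categories([p], self._expressed())
        got = cats.set_index("condition")["category"].to_dict()
        assert got == {
            "leaf_control": "both",
            "leaf_3h": "only_lncRNA",
            "leaf_96h": "only_coding",
            "root_control": "none",
            "root_3h": "both",
            "root_96h": "none",
        }

    def test_missing_member_rejected(self):
        p = _pair(0.9, 0.9, 150)
        p.query_id, p.target_id = "L", "missing"
        with pytest.raises(KeyError, match="missing"):
            coexpression_categories([p], self._expressed())

    def test_category_counts_partition_pairs(self, pipeline_result):
        """Per condition and class, the four category counts sum to the
        number of classified pairs of that class (the published-table
        row-sum property)."""
        cats = pipeline_result["categories"]
        if cats.empty:
            pytest.skip("no pairs in this simulation")
        pairs_df = pipeline_result["pairs_df"]
        table = coexpression_table(cats)
        for klass, sub in table.groupby("pair_class"):
            n_pairs = (pairs_df["pair_class"] == klass).sum()
            sums = sub[["both", "none", "only_coding", "only_lncRNA"]].sum(axis=1)
            assert (sums == n_pairs).all()


class TestExpressionRatio:
    def _fpkm(self, lnc_vals, cod_vals):
        return pd.DataFrame(
            [lnc_vals, cod_vals], index=["L", "C"], columns=list(CONDITIONS)
        )

    def test_equal_fpkm_gives_zero(self):
        p = _pair(0.9, 0.9, 150)
        p.query_id, p.target_id = "L", "C"
        f = self._fpkm([4.0] * 6, [4.0] * 6)
        out = expression_ratio([p], f, {"L"}, epsilon=0.01)
        assert np.allclose(out[list(CONDITIONS)].to_numpy(), 0.0)

    def test_fourfold_lncrna_gives_ratio_two(self):
        p = _pair(0.9, 0.9, 150)
        p.query_id, p.target_id = "L", "C"
        f = self._fpkm([40.0] * 6, [10.0] * 6)
        out = expression_ratio([p], f, {"L"}, epsilon=0.0001)
        assert np.allclose(out[list(CONDITIONS)].to_numpy(), 2.0, atol=1e-3)

    def test_non_de_lncrna_excluded(self):
        p = _pair(0.9, 0.9, 150)
        p.query_id, p.target_id = "L", "C"
        out = expression_ratio([p], self._fpkm([1] * 6, [1] * 6), set())
        assert out.empty

    def test_three_planted_regimes_separate(self, rng):
        """Pairs planted with lncRNA below / equal / above the partner
        separate into three ordered groups by mean ratio."""
        pairs, fpkm_rows, index = [], [], []
        regimes = {"low": 0.25, "mid": 1.0, "high": 4.0}
        for name, mult in regimes.items():
            for i in range(5):
                lid, cid = f"L_{name}{i}", f"C_{name}{i}"
                p = _pair(0.9, 0.9, 150)
                p.query_id, p.target_id = lid, cid
                pairs.append(p)
                base = rng.uniform(5, 50)
                fpkm_rows += [[base * mult] * 6, [base] * 6]
                index += [lid, cid]
        f = pd.DataFrame(fpkm_rows, index=index, columns=list(CONDITIONS))
        out = expression_ratio(pairs, f, {p.query_id for p in pairs})
        means = {
            name: out[out["query_id"].str.contains(name)][list(CONDITIONS)]
            .to_numpy()
            .mean()
            for name in regimes
        }
        assert means["low"] < means["mid"] < means["high"]


class TestTopPaired:
    def test_single_pair(self):
        p = _pair(0.9, 0.9, 150)
        p.query_id = "L1"
        out = top_paired([p], k=5)
        assert out.iloc[0].tolist() == ["L1", 1]

    def test_planted_hub_ranks_first(self, rng):
        pairs = []
        for i in range(10):
            p = _pair(0.9, 0.9, 150)
            p.query_id, p.target_id = "hub", f"C{i}"
            pairs.append(p)
        for i in range(3):
            p = _pair(0.9, 0.9, 150)
            p.query_id, p.target_id = f"L{i}", f"C{i}"
            pairs.append(p)
        out = top_paired(pairs, k=2)
        assert out.iloc[0].tolist() == ["hub", 10]

    def test_k_larger_than_table(self):
        p = _pair(0.9, 0.9, 150)
        p.query_id = "L1"
        assert len(top_paired([p], k=50)) == 1
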