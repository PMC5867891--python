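"""Identification cascade: clustering, screens, predictors, partition."""

import numpy as np
import pytest

from stresslnc.align import global_identity
from stresslnc.catalog import (
    assess_coding,
    call_class,
    cluster_redundant,
    flag_contaminants,
    flag_mirna_precursors,
    run_cascade,
)
from stresslnc.config import PipelineConfig
from stresslnc.models import TranscriptRecord
from stresslnc.orf import HexamerModel, longest_orf

from oracles import greedy_clusters, mirna_scan, revcomp, sw_local


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestClusterRedundant:
    def test_identical_sequences_merge(self):
        cl = cluster_redundant([("a", "ACGT" * 30), ("b", "ACGT" * 30)], 0.90)
        assert len(cl) == 1 and set(cl[0].members) == {"a", "b"}

    def test_identity_boundary_at_90pct(self, rng):
        """Two sequences at 89% global identity stay apart at the 0.90
        threshold; at 91% they merge."""
        base = _rand(rng, 200)
        for n_mut, expect_clusters in ((22, 2), (18, 1)):
            arr = list(base)
            pos = rng.choice(200, size=n_mut, replace=False)
            for p in pos:
                arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
            other = "".join(arr)
            ident = global_identity(base, other)
            cl = cluster_redundant([("a", base), ("b", other)], 0.90)
            assert (len(cl) == expect_clusters) == (
                (ident >= 0.90) == (expect_clusters == 1)
            )

    def test_matches_naive_greedy_oracle(self, rng):
        """Greedy clustering equals a shortcut-free quadratic oracle on 30
        random 150-mers plus planted near-duplicates."""
        records = []
        for i in range(20):
            records.append((f"r{i:02d}", _rand(rng, 150)))
        # plant near-identical copies of some records
        for i in range(10):
            src = records[i][1]
            arr = list(src)
            for p in rng.choice(150, size=int(rng.integers(0, 10)), replace=False):
                arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
            records.append((f"c{i:02d}", "".join(arr)))
        got = [set(c.members) for c in cluster_redundant(records, 0.90)]
        want = greedy_clusters(records, 0.90, global_identity)
        assert got == want

    def test_empty_input(self):
        assert cluster_redundant([], 0.90) == []

    def test_order_independence_of_class_counts(self, rng):
        records = [(f"r{i}", _rand(rng, 120 + i)) for i in range(15)]
        shuffled = list(records)[::-1]
        a = sorted(tuple(sorted(c.members)) for c in cluster_redundant(records, 0.9))
        b = sorted(tuple(sorted(c.members)) for c in cluster_redundant(shuffled, 0.9))
        assert a == b


class TestFlagContaminants:
    def test_copied_transcript_flagged(self, rng):
        ref = _rand(rng, 2000)
        tr = [("t1", ref[300:800]), ("t2", _rand(rng, 500))]
        flags = flag_contaminants(tr, [("ref", ref)])
        assert flags == {"t1": True, "t2": False}

    def test_chimera_below_coverage_rule(self, rng):
        """A transcript that is 40% contaminant remains unflagged under the
        50%-coverage rule; the alignable span agrees with a full
        Smith-Waterman oracle."""
        ref = _rand(rng, 1500)
        chimera = ref[100:300] + _rand(rng, 300)  # 200 / 500 = 40%
        flags = flag_contaminants([("c", chimera)], [("ref", ref)])
        assert flags["c"] is False
        _, (qs, qe), _ = sw_local(chimera, ref)
        assert (qe - qs) / len(chimera) < 0.50

    def test_majority_chimera_flagged(self, rng):
        ref = _rand(rng, 1500)
        chimera = ref[100:400] + _rand(rng, 200)  # 300 / 500 = 60%
        assert flag_contaminants([("c", chimera)], [("ref", ref)])["c"] is True

    def test_empty_reference_flags_nothing(self, rng):
        assert flag_contaminants([("t", _rand(rng, 100))], []) == {"t": False}


class TestAssessCoding:
    def test_planted_long_orf_detected(self, rng):
        cds = "ATG" + "GCT" * 150 + "TAA"
        seq = _rand(rng, 30) + cds + _rand(rng, 30)
        a = assess_coding(seq, None, [])
        assert a.orf_predictor and a.longest_orf_codons >= 150

    def test_short_orfs_only_matches_brute_force(self, rng):
        """ORF predictor agrees with a brute-force codon walk on random
        250-mers (almost always far below 100 codons)."""
        for _ in range(10):
            seq = _rand(rng, 250)
            ncod, _ = longest_orf(seq)
            # brute force over six frames
            best = 0
            for s in (seq, revcomp(seq)):
                for f in range(3):
                    codons = [s[i : i + 3] for i in range(f, len(s) - 2, 3)]
                    start = None
                    for k, c in enumerate(codons):
                        if c in ("TAA", "TAG", "TGA"):
                            if start is not None:
                                best = max(best, k - start + 1)
                                start = None
                        elif c == "ATG" and start is None:
                            start = k
            assert ncod == best
            assert assess_coding(seq, None, []).orf_predictor == (ncod >= 100)

    def test_empty_protein_set_no_homology(self, rng):
        assert assess_coding(_rand(rng, 300), None, []).homology_predictor is False

    def test_homology_against_real_protein(self, rng):
        cds = "ATG" + "GATCTGAAGGAACGT" * 12 + "TAA"
        from Bio.Seq import Seq

        prot = str(Seq(cds).translate()).rstrip("*")
        seq = _rand(rng, 40) + cds + _rand(rng, 40)
        a = assess_coding(seq, None, [("p", prot)])
        assert a.homology_predictor is True

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            assess_coding("ACGTXACGT" * 10, None, [])


class TestCallClass:
    @pytest.mark.parametrize(
        "length,any_pred,expected",
        [
            (200, False, "lncRNA"),
            (199, False, "small_ncRNA"),
            (500, True, "coding_predicted"),
            (150, True, "coding_predicted"),
        ],
    )
    def test_length_and_predictor_rules(self, length, any_pred, expected):
        from stresslnc.models import CodingAssessment

        rec = TranscriptRecord(id="t", sequence="A" * length)
        a = CodingAssessment(any_pred, False, False, 0)
        assert call_class(rec, a, min_len=200) == expected


class TestMirnaPrecursors:
    def test_exact_match_flagged(self, rng):
        lnc = _rand(rng, 300)
        mat = lnc[100:121]
        assert flag_mirna_precursors([("l", lnc)], [("m", mat)])["l"] is True

    def test_two_mismatches_not_flagged(self, rng):
        lnc = _rand(rng, 300)
        mat = list(lnc[100:121])
        mat[3] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mat[3]]
        mat[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mat[10]]
        q = "".join(mat)
        if mirna_scan(lnc, [q], 1):  # mutation accidentally re-matched
            pytest.skip("random sequence contained a 1-mismatch occurrence")
        assert flag_mirna_precursors([("l", lnc)], [("m", q)])["l"] is False

    def test_reverse_complement_detected(self, rng):
        lnc = _rand(rng, 300)
        mat = revcomp(lnc[50:72])
        assert flag_mirna_precursors([("l", lnc)], [("m", mat)])["l"] is True

    def test_matches_sliding_window_oracle(self, rng):
        lncs = [(f"l{i}", _rand(rng, 150)) for i in range(8)]
        mirnas = [(f"m{j}", _rand(rng, 21)) for j in range(5)]
        # embed one real match
        lncs.append(("lx", _rand(rng, 60) + mirnas[0][1] + _rand(rng, 60)))
        got = flag_mirna_precursors(lncs, mirnas, 1)
        for tid, seq in lncs:
            assert got[tid] == mirna_scan(seq, [m for _, m in mirnas], 1)

    def test_query_longer_than_lncrna_skipped(self, rng):
        lnc = _rand(rng, 20)
        assert flag_mirna_precursors([("l", lnc)], [("m", _rand(rng, 25))])["l"] is False


class TestCascade:
    def test_partition_and_counts(self, small_study, pipeline_result):
        """Every input transcript gets exactly one terminal class and the
        class counts sum to the input count."""
        cat = pipeline_result["catalog"]
        truth = small_study["truth"]
        assert len(cat) == len(truth)
        assert cat["terminal_class"].notna().all()
        assert cat["terminal_class"].isin(
            ["contaminant", "protein_match", "coding_predicted", "small_ncRNA", "lncRNA"]
        ).all()
        assert cat["terminal_class"].value_counts().sum() == len(truth)

    def test_min_len_monotonicity(self, rng):
        """Raising the length cutoff never increases the lncRNA count."""
        transcripts = [(f"t{i}", _rand(rng, int(rng.integers(150, 400)))) for i in range(25)]
        counts = []
        for min_len in (150, 200, 250, 300):
            cfg = PipelineConfig(min_lncrna_len=min_len)
            df = run_cascade(transcripts, [], [], [], None, cfg)
            counts.append((df["terminal_class"] == "lncRNA").sum())
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_no_contaminant_survives(self, small_study, pipeline_result):
        """With the contaminant sources in the reference, no planted
        contaminant reaches the lncRNA set."""
        truth = small_study["truth"]
        cat = pipeline_result["catalog"]
        planted = truth.index[truth["label"] == "contaminant"]
        assert (cat.loc[planted, "terminal_class"] == "contaminant").all()
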