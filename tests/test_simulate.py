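"""Synthetic study generator: planted truth, determinism, count model."""

import numpy as np
import pandas as pd
import pytest

from stresslnc.align import revcomp
from stresslnc.models import CONDITIONS
from stresslnc.orf import longest_orf
from stresslnc.simulate import (
    SimParams,
    assign_expression_truth,
    simulate_counts,
    simulate_genome,
    simulate_study,
    simulate_transcripts,
)

from conftest import small_params


class TestSimulateGenome:
    def test_zero_genes_gives_empty_annotation(self):
        _, ann, meta = simulate_genome(1, 50_000, 0, seed=0)
        assert ann.genes == [] and meta == {}

    def test_genes_within_bounds_and_invariants(self):
        genome, ann, meta = simulate_genome(2, 120_000, 20, seed=3)
        assert len(ann.genes) == 20
        sizes = dict(ann.chromosomes)
        for g in ann.genes:
            assert 0 <= g.start < g.end <= sizes[g.chrom]
            assert 1 <= len(g.exons) <= 6
        # the GenomeAnnotation constructor revalidates every invariant
        assert {g.chrom for g in ann.genes} <= set(sizes)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            simulate_genome(1, 30_000, 50, seed=0)

    def test_coding_genes_carry_long_orfs(self):
        _, ann, meta = simulate_genome(1, 100_000, 10, seed=1)
        for gid, m in meta.items():
            ncod, _ = longest_orf(m["mrna"])
            assert ncod >= 100

    def test_byte_identical_rerun(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        simulate_study(a, small_params(seed=5))
        simulate_study(b, small_params(seed=5))
        for name in ("genome.fa", "transcripts.fa", "counts.tsv", "truth.tsv",
                      "aln.bed", "qpcr_ct.tsv"):
            assert (a / name).read_bytes() == (b / name).read_bytes(), name

    def test_wide_intergenic_gaps_exist(self):
        _, ann, _ = simulate_genome(1, 160_000, 16, seed=2)
        genes = sorted(ann.genes, key=lambda g: g.start)
        gaps = [
            genes[i + 1].start - genes[i].end for i in range(len(genes) - 1)
        ]
        assert max(gaps) >= 20_000


class TestSimulateTranscripts:
    def test_invalid_fractions_rejected(self):
        params = small_params()
        params.fractions = {"coding": 0.5, "contaminant": 0.2}
        genome, ann, meta = simulate_genome(1, 120_000, 10, seed=0)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="fractions"):
            simulate_transcripts(genome, ann, meta, params, rng)

    def test_planted_classes_obey_geometry(self, small_study):
        """Intergenic lncRNAs overlap no gene, intronic ones sit strictly
        inside one intron, exon-overlap ones intersect an exon."""
        from stresslnc.io import read_bed12, read_gff3

        truth = small_study["truth"]
        ann = read_gff3(small_study["dir"] / "genes.gff3")
        alns = {a.transcript_id: a for a in read_bed12(small_study["dir"] / "aln.bed")}
        genes = [(g.span, g.exons) for g in ann.genes]
        for t in truth.index[truth["label"] == "lncRNA"]:
            if truth.at[t, "n_placements"] != 1:
                continue
            a = alns[t]
            klass = truth.at[t, "genomic_class"]
            exon_hit = any(
                b[0] < e[1] and e[0] < b[1]
                for (_, exons) in genes
                for e in exons
                for b in a.blocks
            )
            inside = any(
                gs <= a.start and a.end <= ge for ((gs, ge), _) in genes
            )
            if klass == "intergenic":
                assert not exon_hit and not inside
            elif klass == "intronic":
                assert not exon_hit and inside
            else:
                assert exon_hit

    def test_all_intronic_boundary(self):
        params = small_params(seed=9)
        params.n_transcripts = 40
        params.fractions = {
            "coding": 0.25,
            "lnc_intergenic": 0.0,
            "lnc_intronic": 0.75,
            "lnc_exonic": 0.0,
            "redundant": 0.0,
            "contaminant": 0.0,
        }
        params.n_nat_coding = params.n_nat_lnc = params.n_nat_highcov = 0
        params.n_multi_mapped = 0
        genome, ann, meta = simulate_genome(1, 160_000, 10, seed=9)
        rng = np.random.default_rng(9)
        _, _, truth, _, _ = simulate_transcripts(genome, ann, meta, params, rng)
        lnc = truth[truth["label"] == "lncRNA"]
        assert len(lnc) > 0
        assert (lnc["genomic_class"] == "intronic").all()

    def test_planted_nat_window_is_verbatim_revcomp(self, small_study):
        """The reverse complement of each planted pairing window occurs
        verbatim in the partner sequence."""
        from stresslnc.io import read_fasta

        seq_of = dict(read_fasta(small_study["dir"] / "transcripts.fa"))
        nat = small_study["nat_truth"]
        assert len(nat) > 0
        for _, row in nat.iterrows():
            lnc = seq_of[row["lnc_id"]]
            partner = seq_of[row["partner_id"]]
            window = lnc[row["lnc_start"] : row["lnc_end"]]
            assert revcomp(window) in partner

    def test_contaminants_share_no_30mer_with_genome(self, small_study):
        from stresslnc.io import read_fasta

        genome = dict(read_fasta(small_study["dir"] / "genome.fa"))
        kmers = set()
        for seq in genome.values():
            for i in range(len(seq) - 29):
                kmers.add(seq[i : i + 30])
        truth = small_study["truth"]
        seq_of = dict(read_fasta(small_study["dir"] / "transcripts.fa"))
        for t in truth.index[truth["label"] == "contaminant"]:
            s = seq_of[t]
            assert not any(s[i : i + 30] in kmers for i in range(len(s) - 29))

    def test_planted_fold_bounds(self, small_study):
        truth = small_study["truth"]
        de = truth[truth["de_pattern"] != "none"]
        assert (de["true_fold"] >= 4).all()


class TestSimulateCounts:
    def _truth(self, n, rng, **overrides):
        truth = pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "label": "lncRNA",
            }
        ).set_index("transcript_id", drop=False)
        assign_expression_truth(truth, SimParams(), rng)
        for k, v in overrides.items():
            truth[k] = v
        return truth

    def test_dispersion_zero_gives_rounded_means(self, rng):
        truth = self._truth(20, rng)
        a = simulate_counts(truth, (500_000,) * 6, 0.0, 1)
        b = simulate_counts(truth, (500_000,) * 6, 0.0, 1)
        assert a.equals(b)
        assert (a.to_numpy() == np.rint(a.to_numpy())).all()

    def test_early_pattern_multiplies_3h_only(self, rng):
        truth = self._truth(
            1,
            rng,
            base_mean=100.0,
            silent=False,
            de_pattern="early",
            de_tissue="root",
            true_fold=8.0,
            de_direction=1,
        )
        counts = simulate_counts(truth, (500_000,) * 6, 0.0, 123)
        row = counts.iloc[0]
        assert row["root_3h"] >= 4 * row["root_control"]
        # 96 h stays within the non-DE wiggle band
        assert row["root_96h"] < 1.5 * row["root_control"]
        assert row["leaf_3h"] < 1.5 * row["leaf_control"]

    def test_negative_dispersion_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_counts(self._truth(3, rng), (500_000,) * 6, -0.1, 0)

    def test_bad_library_sizes_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_counts(self._truth(3, rng), (1, 2, 3), 0.1, 0)

    def test_silent_transcripts_stay_below_1_fpkm_in_expectation(self, rng):
        truth = self._truth(300, rng)
        counts = simulate_counts(truth, (500_000,) * 6, 0.1, 7)
        lib = counts.sum(axis=0)
        silent = truth.index[truth["silent"]]
        assert len(silent) > 10
        # expected FPKM with typical transcript length 450 nt
        fpkm = counts.loc[silent].mean(axis=1) * 1e9 / (450 * lib.mean())
        assert fpkm.mean() < 1.0

    def test_recovered_fold_matches_planted_within_10pct(self):
        """Geometric-mean observed fold over planted-DE transcripts is
        within 10% of the planted fold (500 transcripts, 20 seeds)."""
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            truth = pd.DataFrame(
                {
                    "transcript_id": [f"t{i}" for i in range(500)],
                    "label": "lncRNA",
                    "base_mean": np.exp(rng.uniform(np.log(100), np.log(1000), 500)),
                    "silent": False,
                    "de_pattern": "none",
                    "de_tissue": "",
                    "true_fold": 0.0,
                    "de_direction": 0,
                }
            ).set_index("transcript_id", drop=False)
            de_ids = truth.index[:50]
            truth.loc[de_ids, ["de_pattern", "de_tissue"]] = ["late", "root"]
            truth.loc[de_ids, "true_fold"] = 8.0
            truth.loc[de_ids, "de_direction"] = 1
            counts = simulate_counts(truth, (500_000,) * 6, 0.1, rng)
            obs = (counts.loc[de_ids, "root_96h"] + 0.5) / (
                counts.loc[de_ids, "root_control"] + 0.5
            )
            ratios.append(np.exp(np.mean(np.log(obs))))
        assert np.mean(ratios) == pytest.approx(8.0, rel=0.10)
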