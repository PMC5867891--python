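"""Synthetic toy study generator with planted, recoverable truth.

Emulates the input side of a stress-transcriptomics lncRNA survey on a
small diploid-free cartoon genome: multi-exon coding genes with planted
ORFs and biased codon usage, planted intergenic / intronic /
exon-overlapping lncRNAs, redundant isoforms, contaminants from a separate
sequence pool, reverse-complement windows shared between transcripts
(trans-NAT truth), conservation tiers across mock reference genomes, a
negative-binomial count matrix for 6 conditions (leaf/root x control, 3 h,
96 h of stress) with planted >=4-fold differential expression in early /
late / prolonged patterns, mature miRNA queries, a GO annotation map and
qPCR Ct tables.

Every random choice flows from one integer seed; reruns are reproducible
byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .align import revcomp
from .models import CONDITIONS, GeneModel, GenomeAnnotation, TranscriptAlignment
from .orf import HexamerModel, longest_orf

ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_FRACTIONS = {
    "coding": 0.15,
    "lnc_intergenic": 0.33,
    "lnc_intronic": 0.10,
    "lnc_exonic": 0.07,
    "redundant": 0.15,
    "contaminant": 0.20,
}

REF_NAMES = ("hybrid_a", "hybrid_b", "hybrid_c")


@dataclass
class SimParams:
    """Study conditions of the synthetic experiment."""

    n_chrom: int = 2
    chrom_len: int = 200_000
    n_genes: int = 60
    n_transcripts: int = 400
    fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    library_sizes: tuple = (500_000,) * 6
    dispersion: float = 0.1
    n_replicates: int = 1  # the study pooled plants; kept for generality
    # DE planting: per tissue-bearing lncRNA, probability of each pattern
    de_pattern_probs: dict = field(
        default_factory=lambda: {"none": 0.70, "early": 0.10, "late": 0.12, "prolonged": 0.08}
    )
    de_folds: tuple = (8.0, 12.0, 16.0)
    silent_fraction: float = 0.12
    n_nat_coding: int = 22
    n_nat_lnc: int = 6
    n_nat_highcov: int = 8
    n_multi_mapped: int = 10
    exclusive_fraction: float = 0.42
    published_fraction: float = 0.25
    seed: int = 0


# ---------------------------------------------------------------------------
# Low-level sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(ALPHABET, size=n).tobytes().decode()


def _weighted_seq(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    return rng.choice(ALPHABET, size=n, p=probs).tobytes().decode()


_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    "".join(c)
    for c in __import__("itertools").product("ACGT", repeat=3)
    if "".join(c) not in _STOPS
)
# Strongly skewed codon weights give coding sequence a hexamer signature
# that the coding-potential filter can learn reliably even on short ORFs;
# the exact preferred-codon pattern is arbitrary.
_CODON_WEIGHTS = np.array(
    [20.0 if i % 3 == 0 else 1.0 for i in range(len(_SENSE_CODONS))], float
)
_CODON_WEIGHTS /= _CODON_WEIGHTS.sum()


def _biased_cds(rng: np.random.Generator, n_codons: int) -> str:
    inner = rng.choice(len(_SENSE_CODONS), size=n_codons, p=_CODON_WEIGHTS)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in inner) + "TAA"


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = ALPHABET[ALPHABET != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _orf_disrupted(seq: str, hex_model, max_codons: int = 95) -> bool:
    """No long ORF on either strand, and any residual ORF scores clearly
    non-coding under the hexamer model (the planted 'disrupted' profile)."""
    ncod, orf = longest_orf(seq)
    if ncod >= max_codons:
        return False
    return not orf or hex_model is None or hex_model.score(orf) < -0.05


def _noncoding_seq(
    rng: np.random.Generator, n: int, probs: np.ndarray, hex_model=None
) -> str:
    """Sequence with coding-like composition but no long ORF on either
    strand and a disrupted hexamer profile."""
    for _ in range(80):
        s = _weighted_seq(rng, n, probs)
        if _orf_disrupted(s, hex_model):
            return s
    raise RuntimeError("could not draw an ORF-free sequence")


# ---------------------------------------------------------------------------
# Free-space bookkeeping for planting loci
# ---------------------------------------------------------------------------

class _FreeSpace:
    """Free intervals on one chromosome, consumed as loci are planted."""

    def __init__(self, length: int, occupied: list[tuple[int, int]], margin: int = 150):
        self.intervals: list[tuple[int, int]] = []
        cur = margin
        for s, e in sorted(occupied):
            if s - cur > 0:
                self.intervals.append((cur, s))
            cur = max(cur, e)
        if length - margin - cur > 0:
            self.intervals.append((cur, length - margin))

    def allocate(self, rng: np.random.Generator, length: int, pad: int = 120):
        need = length + 2 * pad
        viable = [i for i, (s, e) in enumerate(self.intervals) if e - s >= need]
        if not viable:
            return None
        i = int(rng.choice(viable))
        s, e = self.intervals[i]
        start = int(rng.integers(s + pad, e - pad - length + 1))
        self._carve(i, start - pad, start + length + pad)
        return start

    def allocate_at(self, start: int, length: int, pad: int = 100) -> bool:
        lo, hi = start, start + length + pad
        for i, (s, e) in enumerate(self.intervals):
            if s <= lo and hi <= e:
                self._carve(i, lo, hi)
                return True
        return False

    def _carve(self, i: int, lo: int, hi: int) -> None:
        s, e = self.intervals.pop(i)
        if hi < e:
            self.intervals.insert(i, (hi, e))
        if lo > s:
            self.intervals.insert(i, (s, lo))

    def min_gap_to(self, pos: int) -> int:
        return min(
            (abs(pos - s) for s, e in self.intervals), default=10**9
        )


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

def simulate_genome(
    n_chrom: int, chrom_len: int, n_genes: int, seed: int | np.random.Generator
):
    """Simulate a random genome with planted multi-exon coding genes.

    Returns ``(genome, annotation, gene_meta)`` where ``genome`` is a list
    of (name, sequence) pairs, ``annotation`` a :class:`GenomeAnnotation`,
    and ``gene_meta`` per-gene details (mRNA sequence, UTR lengths,
    protein) needed by transcript planting. Genes carry 1-6 exons; a third
    of inter-gene gaps are wide (>= 20 kb) so that far-intergenic loci can
    be planted. Raises if the requested genes cannot be packed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genome: dict[str, bytearray] = {}
    genes: list[GeneModel] = []
    gene_meta: dict[str, dict] = {}
    per_chrom = [n_genes // n_chrom + (1 if c < n_genes % n_chrom else 0) for c in range(n_chrom)]
    gidx = 0
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        seq = bytearray(_random_seq(rng, chrom_len).encode())
        genome[name] = seq
        cursor = 3000 + int(rng.integers(0, 1500))
        n_here = per_chrom[c]
        big_gap_after = {n_here // 3, (2 * n_here) // 3} if n_here >= 3 else set()
        for gi in range(n_here):
            n_ex = int(rng.integers(1, 7))
            ex_lens = [int(rng.integers(180, 421)) for _ in range(n_ex)]
            if sum(ex_lens) < 380:  # guarantee room for a >100-codon ORF
                ex_lens = [max(l, 380 // n_ex + 1) for l in ex_lens]
            in_lens = [int(rng.integers(250, 901)) for _ in range(n_ex - 1)]
            span = sum(ex_lens) + sum(in_lens)
            if cursor + span > chrom_len - 3000:
                raise ValueError(
                    f"infeasible gene packing: {n_genes} genes do not fit "
                    f"{n_chrom} x {chrom_len} bp"
                )
            exons = []
            pos = cursor
            for k, el in enumerate(ex_lens):
                exons.append((pos, pos + el))
                pos += el + (in_lens[k] if k < len(in_lens) else 0)
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"G{gidx + 1:03d}"
            L = sum(ex_lens)
            u5 = int(rng.integers(20, 41))
            u3 = int(rng.integers(170, 261)) if L - u5 - 320 >= 170 else L - u5 - 320
            cds_codons = (L - u5 - u3) // 3
            cds = _biased_cds(rng, cds_codons - 2)
            u3 = L - u5 - len(cds)  # absorb rounding into the 3' UTR
            mrna = _random_seq(rng, u5) + cds + _random_seq(rng, u3)
            genomic = mrna if strand == "+" else revcomp(mrna)
            off = 0
            for s, e in exons:
                seq[s:e] = genomic[off : off + (e - s)].encode()
                off += e - s
            from Bio.Seq import Seq

            genes.append(GeneModel(gene_id, name, strand, exons, "coding"))
            gene_meta[gene_id] = {
                "mrna": mrna,
                "u5": u5,
                "u3": u3,
                "cds_start": u5,
                "cds_end": u5 + len(cds),
                "protein": str(Seq(cds).translate()).rstrip("*"),
                "strand": strand,
            }
            gap = (
                int(rng.integers(20_000, 23_001))
                if gi in big_gap_after
                else int(rng.integers(800, 2201))
            )
            cursor = pos + gap
            gidx += 1
    annotation = GenomeAnnotation(
        chromosomes=[(f"chr{c + 1}", chrom_len) for c in range(n_chrom)],
        genes=genes,
    )
    return genome, annotation, gene_meta


# ---------------------------------------------------------------------------
# Transcript catalog with planted truth
# ---------------------------------------------------------------------------

def _label_counts(fractions: dict, n: int, n_genes: int) -> dict[str, int]:
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    raw = {k: fractions[k] * n for k in fractions}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    rest = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:rest]:
        counts[k] += 1
    counts["coding"] = min(counts.get("coding", 0), n_genes)
    return counts


def simulate_transcripts(
    genome: dict[str, bytearray],
    annotation: GenomeAnnotation,
    gene_meta: dict,
    params: SimParams,
    rng: np.random.Generator,
):
    """Plant the transcript catalog; mutates ``genome`` at planted loci.

    Returns ``(records, alignments, truth, nat_truth, aux)`` where
    ``records`` is a list of (id, sequence), ``alignments`` the true BED12
    placements, ``truth`` a per-transcript DataFrame, ``nat_truth`` the
    planted pairing-region table and ``aux`` extra fixture material
    (proteins, contaminant refs, miRNAs).
    """
    counts = _label_counts(params.fractions, params.n_transcripts, params.n_genes)
    coding_probs = _coding_composition(gene_meta)
    hex_model = (
        HexamerModel.train_from_coding([m["mrna"] for m in gene_meta.values()], rng)
        if gene_meta
        else None
    )
    free = {
        name: _FreeSpace(
            length,
            [(g.start, g.end) for g in annotation.genes_on(name)],
        )
        for name, length in annotation.chromosomes
    }
    records: list[tuple[str, str]] = []
    alignments: list[TranscriptAlignment] = []
    rows: list[dict] = []

    def row(tid, label, **kw):
        base = {
            "transcript_id": tid,
            "label": label,
            "genomic_class": "",
            "spliced": False,
            "n_placements": 0,
            "parent": "",
            "nat_partner": "",
            "nat_target_type": "",
            "nat_window_len": 0,
            "mirna_precursor": False,
        }
        base.update(kw)
        rows.append(base)

    # --- coding transcripts: one per gene -------------------------------
    gene_ids = [g.gene_id for g in annotation.coding_genes()]
    coding_gene_ids = list(rng.choice(gene_ids, size=counts["coding"], replace=False))
    tid_of_gene: dict[str, str] = {}
    for i, gid in enumerate(sorted(coding_gene_ids)):
        tid = f"TC{i + 1:04d}"
        tid_of_gene[gid] = tid
        g = next(g for g in annotation.genes if g.gene_id == gid)
        records.append((tid, gene_meta[gid]["mrna"]))
        alignments.append(TranscriptAlignment(tid, g.chrom, list(g.exons)))
        row(
            tid,
            "coding",
            genomic_class="exonic_overlap",
            spliced=len(g.exons) >= 2,
            n_placements=1,
            gene_id=gid,
        )

    # --- planted lncRNAs -------------------------------------------------
    # exon-overlap loci need the space right next to gene ends, so they
    # are planted before intergenic loci fragment it
    lnc_specs = (
        [("exonic_overlap", None)] * counts["lnc_exonic"]
        + [("intronic", None)] * counts["lnc_intronic"]
        + [("intergenic", None)] * counts["lnc_intergenic"]
    )
    lnc_idx = 0
    used_introns: set[tuple[str, int]] = set()
    used_exonic_genes: set[str] = set()
    chrom_names = [n for n, _ in annotation.chromosomes]
    for klass, _ in lnc_specs:
        tid = f"TL{lnc_idx + 1:04d}"
        lnc_idx += 1
        planted = False
        for _attempt in range(40):
            if klass == "intergenic":
                chrom = str(rng.choice(chrom_names))
                n_blocks = 1 if rng.random() < 0.6 else int(rng.integers(2, 5))
                blk_lens = [int(rng.integers(160, 420)) for _ in range(n_blocks)]
                if n_blocks == 1:
                    blk_lens = [int(rng.integers(250, 701))]
                in_lens = [int(rng.integers(80, 301)) for _ in range(n_blocks - 1)]
                span = sum(blk_lens) + sum(in_lens)
                start = free[chrom].allocate(rng, span)
                if start is None:
                    continue
                blocks = []
                pos = start
                for k, bl in enumerate(blk_lens):
                    blocks.append((pos, pos + bl))
                    pos += bl + (in_lens[k] if k < len(in_lens) else 0)
                seq = _noncoding_seq(rng, sum(blk_lens), coding_probs, hex_model)
                off = 0
                for s, e in blocks:
                    genome[chrom][s:e] = seq[off : off + (e - s)].encode()
                    off += e - s
            elif klass == "intronic":
                candidates = [
                    (g, ii, iv)
                    for g in annotation.coding_genes()
                    for ii, iv in enumerate(g.introns())
                    if iv[1] - iv[0] >= 420 and (g.gene_id, ii) not in used_introns
                ]
                if not candidates:
                    break
                g, ii, (ivs, ive) = candidates[int(rng.integers(len(candidates)))]
                length = int(rng.integers(220, min(650, ive - ivs - 60) + 1))
                start = int(rng.integers(ivs + 25, ive - 25 - length + 1))
                used_introns.add((g.gene_id, ii))
                chrom = g.chrom
                blocks = [(start, start + length)]
                seq = _noncoding_seq(rng, length, coding_probs, hex_model)
                genome[chrom][start : start + length] = seq.encode()
            else:  # exonic_overlap at the 3' UTR end of a gene
                candidates = [
                    g
                    for g in annotation.coding_genes()
                    if gene_meta[g.gene_id]["u3"] >= 60
                    and g.gene_id not in used_exonic_genes
                ]
                if not candidates:
                    break
                g = candidates[int(rng.integers(len(candidates)))]
                meta = gene_meta[g.gene_id]
                last_len = (
                    g.exons[-1][1] - g.exons[-1][0]
                    if meta["strand"] == "+"
                    else g.exons[0][1] - g.exons[0][0]
                )
                ov = int(rng.integers(40, min(121, meta["u3"], last_len - 5) + 1))
                length = int(rng.integers(max(250, ov + 120), 651))
                if meta["strand"] == "+":
                    start = g.exons[-1][1] - ov
                    outside = (g.exons[-1][1], start + length)
                else:
                    end = g.exons[0][0] + ov
                    start = end - length
                    outside = (start, g.exons[0][0])
                chrom = g.chrom
                if not free[chrom].allocate_at(outside[0], outside[1] - outside[0]):
                    continue
                used_exonic_genes.add(g.gene_id)
                blocks = [(start, start + length)]
                filler = _noncoding_seq(rng, outside[1] - outside[0], coding_probs, hex_model)
                genome[chrom][outside[0] : outside[1]] = filler.encode()
                seq = genome[chrom][start : start + length].decode()
                if not _orf_disrupted(seq, hex_model):
                    continue  # UTR fragment made a coding-like ORF; retry
            planted = True
            break
        if not planted:
            continue
        alignments.append(TranscriptAlignment(tid, chrom, blocks))
        records.append((tid, seq))
        row(
            tid,
            "lncRNA",
            genomic_class=klass,
            spliced=len(blocks) >= 2,
            n_placements=1,
        )

    truth = pd.DataFrame(rows).set_index("transcript_id", drop=False)

    # --- trans-NAT planting ---------------------------------------------
    nat_truth = _plant_nats(
        genome, annotation, gene_meta, tid_of_gene, records, alignments, truth,
        params, rng, hex_model
    )

    # --- multi-mapped copies --------------------------------------------
    single_lnc = [
        a
        for a in alignments
        if a.transcript_id.startswith("TL")
        and len(a.blocks) == 1
        and truth.loc[a.transcript_id, "nat_partner"] == ""
    ]
    rng.shuffle(single_lnc)
    n_multi = min(params.n_multi_mapped, len(single_lnc))
    for a in single_lnc[:n_multi]:
        seq = dict(records)[a.transcript_id]
        for chrom in chrom_names:
            start = free[chrom].allocate(rng, len(seq))
            if start is not None:
                genome[chrom][start : start + len(seq)] = seq.encode()
                alignments.append(
                    TranscriptAlignment(a.transcript_id, chrom, [(start, start + len(seq))])
                )
                truth.loc[a.transcript_id, "n_placements"] = 2
                break

    # --- redundant isoforms ---------------------------------------------
    parent_pool = [r for r in records if r[0][:2] in ("TC", "TL")]
    for i in range(counts["redundant"]):
        pid, pseq = parent_pool[int(rng.integers(len(parent_pool)))]
        trunc = int(len(pseq) * rng.uniform(0.03, 0.08))
        iso = _mutate(rng, pseq[trunc:], 0.01)
        tid = f"TR{i + 1:04d}"
        records.append((tid, iso))
        new = pd.Series(
            {
                "transcript_id": tid,
                "label": "redundant",
                "genomic_class": "",
                "spliced": False,
                "n_placements": 0,
                "parent": pid,
                "nat_partner": "",
                "nat_target_type": "",
                "nat_window_len": 0,
                "mirna_precursor": False,
            }
        )
        truth.loc[tid] = new

    # --- contaminants ----------------------------------------------------
    cont_refs = [(f"CONTREF{j + 1}", _random_seq(rng, 6000)) for j in range(3)]
    genome_kmers = _genome_kmer_set(genome, 30)
    for i in range(counts["contaminant"]):
        for _ in range(30):
            ref_name, ref_seq = cont_refs[int(rng.integers(len(cont_refs)))]
            length = int(rng.integers(300, 701))
            start = int(rng.integers(0, len(ref_seq) - length + 1))
            seq = _mutate(rng, ref_seq[start : start + length], 0.005)
            if not _shares_kmer(seq, genome_kmers, 30):
                break
        tid = f"TX{i + 1:04d}"
        records.append((tid, seq))
        truth.loc[tid] = pd.Series(
            {
                "transcript_id": tid,
                "label": "contaminant",
                "genomic_class": "",
                "spliced": False,
                "n_placements": 0,
                "parent": "",
                "nat_partner": "",
                "nat_target_type": "",
                "nat_window_len": 0,
                "mirna_precursor": False,
            }
        )

    # --- mature miRNA queries -------------------------------------------
    mirnas = _plant_mirnas(records, truth, rng)

    truth["length"] = [len(dict(records)[t]) for t in truth.index]
    aux = {
        "proteins": [
            (f"P_{gid}", gene_meta[gid]["protein"]) for gid in sorted(tid_of_gene)
        ],
        "coding_ref": [(tid_of_gene[gid], gene_meta[gid]["mrna"]) for gid in sorted(tid_of_gene)],
        "contaminant_refs": cont_refs,
        "mirnas": mirnas,
        "tid_of_gene": tid_of_gene,
    }
    return records, alignments, truth, nat_truth, aux


def _coding_composition(gene_meta: dict) -> np.ndarray:
    joined = "".join(m["mrna"] for m in gene_meta.values()) or "ACGT"
    arr = np.frombuffer(joined.encode(), dtype=np.uint8)
    probs = np.array([(arr == b).mean() for b in ALPHABET])
    return probs / probs.sum()


def _genome_kmer_set(genome: dict[str, bytearray], k: int) -> set[bytes]:
    kmers: set[bytes] = set()
    for seq in genome.values():
        b = bytes(seq)
        for i in range(0, len(b) - k + 1):
            kmers.add(b[i : i + k])
    return kmers


def _shares_kmer(seq: str, kmers: set[bytes], k: int) -> bool:
    b = seq.encode()
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def _plant_nats(
    genome, annotation, gene_meta, tid_of_gene, records, alignments, truth,
    params, rng, hex_model=None
) -> pd.DataFrame:
    """Overwrite windows of chosen lncRNAs with reverse complements of
    partner windows; update records in place and return pair truth."""
    seq_of = dict(records)
    aln_of = {a.transcript_id: a for a in alignments if len(a.blocks) == 1}
    eligible = [
        t
        for t in truth.index
        if truth.loc[t, "label"] == "lncRNA"
        and truth.loc[t, "genomic_class"] == "intergenic"
        and not truth.loc[t, "spliced"]
        and t in aln_of
    ]
    rng.shuffle(eligible)
    pairs: list[dict] = []
    used: set[str] = set()

    def set_window(lnc_id: str, window: str, partner_id: str, ttype: str, pstart: int):
        a = aln_of[lnc_id]
        seq = seq_of[lnc_id]
        w = len(window)
        if w >= len(seq) - 20:
            return False
        off = int(rng.integers(10, len(seq) - w - 10 + 1))
        new_seq = seq[:off] + revcomp(window) + seq[off + w :]
        if not _orf_disrupted(new_seq, hex_model):
            return False
        s = a.blocks[0][0]
        genome[a.chrom][s : s + len(new_seq)] = new_seq.encode()
        seq_of[lnc_id] = new_seq
        truth.loc[lnc_id, ["nat_partner", "nat_target_type", "nat_window_len"]] = [
            partner_id,
            ttype,
            w,
        ]
        used.add(lnc_id)
        used.add(partner_id)
        pairs.append(
            {
                "lnc_id": lnc_id,
                "partner_id": partner_id,
                "target_type": ttype,
                "lnc_start": off,
                "lnc_end": off + w,
                "partner_start": pstart,
                "partner_end": pstart + w,
                "window_len": w,
            }
        )
        return True

    # lncRNA -> coding 3' UTR windows ("100 nt"-class pairs)
    utr_genes = [g for g in sorted(tid_of_gene) if gene_meta[g]["u3"] >= 140]
    it = iter(eligible)
    made = 0
    while made < params.n_nat_coding and utr_genes:
        try:
            lnc = next(it)
        except StopIteration:
            break
        gid = utr_genes[int(rng.integers(len(utr_genes)))]
        meta = gene_meta[gid]
        w = int(rng.integers(120, min(171, meta["u3"]) + 1))
        u3_start = meta["cds_end"]
        pstart = int(rng.integers(u3_start, u3_start + meta["u3"] - w + 1))
        window = meta["mrna"][pstart : pstart + w]
        if set_window(lnc, window, tid_of_gene[gid], "coding", pstart):
            made += 1

    # lncRNA -> lncRNA window pairs
    remaining = [t for t in eligible if t not in used]
    made = 0
    i = 0
    while made < params.n_nat_lnc and i + 1 < len(remaining):
        a_id, b_id = remaining[i], remaining[i + 1]
        i += 2
        bseq = seq_of[b_id]
        w = int(rng.integers(120, min(171, len(bseq) - 40) + 1))
        pstart = int(rng.integers(10, len(bseq) - w - 10 + 1))
        if set_window(a_id, bseq[pstart : pstart + w], b_id, "lncRNA", pstart):
            made += 1

    # high-coverage lncRNA-lncRNA pairs: B's core is revcomp of most of A.
    # Adjacent members of the length-sorted pool have similar lengths, so a
    # window of 62% of the longer member exceeds half of BOTH lengths.
    remaining = sorted(
        (t for t in eligible if t not in used), key=lambda t: len(seq_of[t])
    )
    made = 0
    i = 0
    while made < params.n_nat_highcov and i + 1 < len(remaining):
        a_id, b_id = remaining[i], remaining[i + 1]
        i += 2
        aseq, bseq = seq_of[a_id], seq_of[b_id]
        w = int(0.62 * max(len(aseq), len(bseq)))
        if w < 120 or w > min(len(aseq), len(bseq)) - 45:
            continue
        astart = (len(aseq) - w) // 2
        if set_window(b_id, aseq[astart : astart + w], a_id, "lncRNA", astart):
            made += 1

    for i, (tid, _) in enumerate(records):
        if tid in seq_of:
            records[i] = (tid, seq_of[tid])
    return pd.DataFrame(pairs)


def _plant_mirnas(records, truth, rng) -> list[tuple[str, str]]:
    seq_of = dict(records)
    plain = [
        t
        for t in truth.index
        if truth.loc[t, "label"] == "lncRNA" and truth.loc[t, "nat_partner"] == ""
    ]
    rng.shuffle(plain)
    mirnas: list[tuple[str, str]] = []
    # two exact embeddings, two 1-mismatch embeddings (flagged), one
    # 2-mismatch decoy (not flagged)
    for j, (n_mm, flagged) in enumerate([(0, True), (0, True), (1, True), (1, True), (2, False)]):
        if j >= len(plain):
            break
        t = plain[j]
        seq = seq_of[t]
        start = int(rng.integers(0, len(seq) - 21 + 1))
        mat = seq[start : start + 21]
        arr = np.frombuffer(mat.encode(), dtype=np.uint8).copy()
        pos = rng.choice(21, size=n_mm, replace=False)
        for p in pos:
            arr[p] = rng.choice(ALPHABET[ALPHABET != arr[p]])
        mirnas.append((f"miR{j + 1:02d}", arr.tobytes().decode()))
        if flagged:
            truth.loc[t, "mirna_precursor"] = True
    for j in range(3):
        mirnas.append((f"miRrand{j + 1}", _random_seq(rng, int(rng.integers(18, 27)))))
    return mirnas


# ---------------------------------------------------------------------------
# Conservation references
# ---------------------------------------------------------------------------

def simulate_references(records, truth, params: SimParams, rng: np.random.Generator):
    """Assign conservation tiers and build mock reference sequence sets.

    Each called-lncRNA candidate is conserved in a random subset of the
    three mock hybrids (empty subset = exclusive, with probability
    ``exclusive_fraction``); hybrids a/b are genome-mode references
    (mutated copies embedded in random filler), hybrid c is a read-set
    reference (tiled 100-mers). A fraction of lncRNAs also appears in a
    mock published lncRNA catalog (near-full-length copies).
    """
    seq_of = dict(records)
    lnc_ids = [t for t in truth.index if truth.loc[t, "label"] == "lncRNA"]
    tiers: dict[str, tuple[str, ...]] = {}
    subsets = [
        ("hybrid_a",),
        ("hybrid_b",),
        ("hybrid_c",),
        ("hybrid_a", "hybrid_b"),
        ("hybrid_a", "hybrid_c"),
        ("hybrid_b", "hybrid_c"),
        ("hybrid_a", "hybrid_b", "hybrid_c"),
    ]
    members: dict[str, list[str]] = {r: [] for r in REF_NAMES}
    published: list[tuple[str, str]] = []
    for t in lnc_ids:
        if rng.random() < params.exclusive_fraction:
            tiers[t] = ()
        else:
            tier = subsets[int(rng.integers(len(subsets)))]
            tiers[t] = tier
            for r in tier:
                members[r].append(t)
        if rng.random() < params.published_fraction:
            seq = seq_of[t]
            keep = int(len(seq) * rng.uniform(0.95, 1.0))
            start = int(rng.integers(0, len(seq) - keep + 1))
            published.append((f"PUB_{t}", _mutate(rng, seq[start : start + keep], 0.01)))
    refs: dict[str, list[tuple[str, str]]] = {}
    for r in ("hybrid_a", "hybrid_b"):
        chunks = [_random_seq(rng, 4000)]
        for t in members[r]:
            chunks.append(_mutate(rng, seq_of[t], 0.01))
            chunks.append(_random_seq(rng, 300))
        refs[r] = [(f"{r}_contig1", "".join(chunks))]
    reads: list[tuple[str, str]] = []
    for t in members["hybrid_c"]:
        copy = _mutate(rng, seq_of[t], 0.01)
        for j, s in enumerate(range(0, max(1, len(copy) - 100 + 1), 50)):
            reads.append((f"rd_{t}_{j}", copy[s : s + 100]))
    refs["hybrid_c"] = reads
    truth["conserved_refs"] = [
        ";".join(tiers.get(t, ())) if t in tiers else "" for t in truth.index
    ]
    truth["exclusive"] = [
        (truth.loc[t, "label"] == "lncRNA" and len(tiers.get(t, ())) == 0)
        for t in truth.index
    ]
    truth["in_published_set"] = [
        any(p[0] == f"PUB_{t}" for p in published) for t in truth.index
    ]
    return refs, published, tiers


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def assign_expression_truth(truth: pd.DataFrame, params: SimParams, rng) -> None:
    """Attach base means and DE patterns to the truth table in place."""
    n = len(truth)
    labels = truth["label"].to_numpy()
    base = np.exp(rng.uniform(np.log(150), np.log(2000), size=n))
    silent = rng.random(n) < params.silent_fraction
    base[silent] = 0.05
    patterns = np.array(["none"] * n, dtype=object)
    tissues = np.array([""] * n, dtype=object)
    folds = np.zeros(n)
    directions = np.zeros(n, dtype=int)
    names = list(params.de_pattern_probs)
    probs = np.array([params.de_pattern_probs[k] for k in names])
    for i in range(n):
        if labels[i] != "lncRNA" or silent[i]:
            continue
        p = str(rng.choice(names, p=probs))
        if p == "none":
            continue
        patterns[i] = p
        tissues[i] = "leaf" if rng.random() < 0.5 else "root"
        folds[i] = float(rng.choice(params.de_folds))
        directions[i] = 1 if rng.random() < 0.5 else -1
        base[i] = np.exp(rng.uniform(np.log(300), np.log(3000)))
    truth["base_mean"] = base
    truth["silent"] = silent
    truth["de_pattern"] = patterns
    truth["de_tissue"] = tissues
    truth["true_fold"] = folds
    truth["de_direction"] = directions


def condition_multipliers(truth: pd.DataFrame, rng) -> pd.DataFrame:
    """Per-transcript per-condition mean multipliers implied by the truth."""
    mult = pd.DataFrame(1.0, index=truth.index, columns=list(CONDITIONS))
    wiggle = rng.uniform(0.9, 1.12, size=(len(truth), 4))
    stress_cols = ["leaf_3h", "leaf_96h", "root_3h", "root_96h"]
    for j, c in enumerate(stress_cols):
        mult[c] = wiggle[:, j]
    for t in truth.index:
        p = truth.loc[t, "de_pattern"]
        if p == "none":
            continue
        tis = truth.loc[t, "de_tissue"]
        f = truth.loc[t, "true_fold"] ** truth.loc[t, "de_direction"]
        if p in ("early", "prolonged"):
            mult.loc[t, f"{tis}_3h"] = f
        if p in ("late", "prolonged"):
            mult.loc[t, f"{tis}_96h"] = f
    return mult


def simulate_counts(
    truth: pd.DataFrame,
    library_sizes,
    dispersion: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw the 6-condition count matrix from the planted truth.

    Counts follow a negative-binomial model with per-transcript base mean,
    condition multiplier equal to the planted fold inside the planted
    stress window, and a shared dispersion. ``dispersion = 0`` degenerates
    to noise-free rounded means.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    lib = np.asarray(library_sizes, dtype=float)
    if lib.shape != (6,) or (lib <= 0).any():
        raise ValueError("need 6 positive library sizes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mult = condition_multipliers(truth, rng)
    means = (
        truth["base_mean"].to_numpy()[:, None]
        * mult.to_numpy()
        * (lib / lib.mean())[None, :]
    )
    if dispersion == 0:
        counts = np.rint(means).astype(int)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + means))
    return pd.DataFrame(counts, index=truth.index, columns=list(CONDITIONS))


# ---------------------------------------------------------------------------
# GO map and qPCR fixtures
# ---------------------------------------------------------------------------

GO_TERMS = [
    ("GO:0006355", "regulation of transcription", "biological_process"),
    ("GO:0006950", "response to stress", "biological_process"),
    ("GO:0009628", "response to abiotic stimulus", "biological_process"),
    ("GO:0030410", "nicotianamine synthase activity", "molecular_function"),
    ("GO:0003700", "DNA-binding transcription factor activity", "molecular_function"),
    ("GO:0016301", "kinase activity", "molecular_function"),
    ("GO:0005215", "transporter activity", "molecular_function"),
    ("GO:0008152", "metabolic process", "biological_process"),
    ("GO:0006810", "transport", "biological_process"),
    ("GO:0003824", "catalytic activity", "molecular_function"),
]


def simulate_go_map(truth: pd.DataFrame, aux: dict, rng) -> pd.DataFrame:
    """Annotate coding genes with GO terms; trans-NAT targets are biased
    toward the stress/transcription terms so enrichment is recoverable."""
    tid_of_gene = aux["tid_of_gene"]
    nat_targets = set(truth.loc[truth["nat_target_type"] == "coding", "nat_partner"])
    rows = []
    enriched_terms = GO_TERMS[:4]
    for gid, tid in sorted(tid_of_gene.items()):
        terms = set()
        for term in GO_TERMS:
            p = 0.15
            if term in enriched_terms and tid in nat_targets:
                p = 0.75
            if rng.random() < p:
                terms.add(term)
        if not terms:
            terms.add(GO_TERMS[int(rng.integers(4, len(GO_TERMS)))])
        for term_id, name, ns in sorted(terms):
            rows.append({"gene": tid, "term": term_id, "namespace": ns, "name": name})
    return pd.DataFrame(rows)


def simulate_qpcr(truth: pd.DataFrame, rng, n_targets: int = 12):
    """Ct tables for a subset of planted-DE lncRNAs plus a reference gene.

    Ct values encode the planted log2 fold changes (ideal 100% efficiency,
    Ct drop of 1 per doubling) with replicate noise; the dilution table is
    a 1:2 series from 32 ng with the ideal slope.
    """
    de = truth[(truth["de_pattern"] != "none")].index.tolist()
    targets = de[: min(n_targets, len(de))]
    rows = []
    ref_ct = 20.0
    times = ["control", "3h", "96h"]
    for t in targets:
        tis = truth.loc[t, "de_tissue"]
        pattern = truth.loc[t, "de_pattern"]
        lf = math.log2(truth.loc[t, "true_fold"]) * truth.loc[t, "de_direction"]
        base_ct = 24.0 + rng.uniform(-1, 1)
        for time in times:
            active = (pattern in ("early", "prolonged") and time == "3h") or (
                pattern in ("late", "prolonged") and time == "96h"
            )
            ct_t = base_ct - (lf if active else 0.0)
            for br in (1, 2, 3):
                bio_shift = rng.normal(0, 0.12)
                for tr in (1, 2, 3):
                    rows.append(
                        dict(
                            target=t,
                            tissue=tis,
                            time=time,
                            bio_rep=br,
                            tech_rep=tr,
                            ct=round(ct_t + bio_shift + rng.normal(0, 0.06), 3),
                        )
                    )
                    rows.append(
                        dict(
                            target="REF_CUL",
                            tissue=tis,
                            time=time,
                            bio_rep=br,
                            tech_rep=tr,
                            ct=round(ref_ct + bio_shift + rng.normal(0, 0.06), 3),
                        )
                    )
    ct_table = pd.DataFrame(rows).drop_duplicates(
        subset=["target", "tissue", "time", "bio_rep", "tech_rep"]
    )
    dil_rows = []
    for t in (targets[:3] + ["REF_CUL"]) if targets else ["REF_CUL"]:
        for j in range(6):
            log_input = math.log10(32.0 / (2**j))
            dil_rows.append(
                dict(
                    target=t,
                    log10_input=round(log_input, 5),
                    ct=round(18.0 - 3.321928 * log_input + rng.normal(0, 0.04), 3),
                )
            )
    return ct_table, pd.DataFrame(dil_rows)


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def simulate_study(outdir: str | Path, params: SimParams | None = None, seed: int | None = None):
    """Generate the complete fixture set under one directory.

    Writes genome.fa, genes.gff3, transcripts.fa, aln.bed, counts.tsv,
    mirnas.fa, proteins.fa, coding_ref.fa, contaminants.fa, go_map.tsv,
    qpcr_ct.tsv, qpcr_dilution.tsv, truth.tsv, nat_truth.tsv and the
    conservation reference FASTAs under refs/. Returns the truth table and
    parameter record.
    """
    params = params or SimParams()
    if seed is not None:
        params.seed = seed
    rng = np.random.default_rng(params.seed)
    outdir = Path(outdir)
    (outdir / "refs").mkdir(parents=True, exist_ok=True)

    genome, annotation, gene_meta = simulate_genome(
        params.n_chrom, params.chrom_len, params.n_genes, rng
    )
    records, alignments, truth, nat_truth, aux = simulate_transcripts(
        genome, annotation, gene_meta, params, rng
    )
    refs, published, _ = simulate_references(records, truth, params, rng)
    assign_expression_truth(truth, params, rng)
    counts = simulate_counts(truth, params.library_sizes, params.dispersion, rng)
    go_map = simulate_go_map(truth, aux, rng)
    ct_table, dilution = simulate_qpcr(truth, rng)

    order = rng.permutation(len(records))
    shuffled = [records[i] for i in order]

    sio.write_fasta(outdir / "genome.fa", [(n, bytes(s).decode()) for n, s in genome.items()])
    sio.write_gff3(outdir / "genes.gff3", annotation)
    sio.write_fasta(outdir / "transcripts.fa", shuffled)
    sio.write_bed12(outdir / "aln.bed", alignments)
    sio.write_counts(outdir / "counts.tsv", counts)
    sio.write_fasta(outdir / "mirnas.fa", aux["mirnas"])
    sio.write_fasta(outdir / "proteins.fa", aux["proteins"])
    sio.write_fasta(outdir / "coding_ref.fa", aux["coding_ref"])
    sio.write_fasta(outdir / "contaminants.fa", aux["contaminant_refs"])
    sio.write_fasta(outdir / "published_lncrnas.fa", published)
    for r, recs in refs.items():
        sio.write_fasta(outdir / "refs" / f"{r}.fa", recs)
    go_map.to_csv(outdir / "go_map.tsv", sep="\t", index=False)
    ct_table.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    dilution.to_csv(outdir / "qpcr_dilution.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    nat_truth.to_csv(outdir / "nat_truth.tsv", sep="\t", index=False)
    return truth, nat_truth, params
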