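"""Non-redundant transcript catalog and the lncRNA identification cascade.

The cascade mirrors the standard plant-lncRNA discovery recipe: greedy
redundancy clustering at 90% global identity, a contaminant screen against
a foreign-sequence reference, a protein-database screen, three
coding-potential predictors (longest ORF, hexamer usage bias, protein
homology) combined by an "any predictor => coding" rule, a 200-nt length
split between small ncRNAs and lncRNAs, and a mature-miRNA precursor scan
allowing a single mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import (
    KmerIndex,
    covered_fraction,
    global_identity,
    protein_local_score,
    revcomp,
    seed_blocks,
    shared_peptide_kmer,
    translate_frames,
)
from .config import PipelineConfig
from .models import CodingAssessment, TranscriptRecord
from .orf import HexamerModel, longest_orf


# ---------------------------------------------------------------------------
# Redundancy clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    representative: str
    members: list[str]  # includes the representative


def cluster_redundant(
    transcripts: list[tuple[str, str]], identity: float = 0.90
) -> list[Cluster]:
    """Greedy longest-first clustering at a global-identity threshold.

    Transcripts are visited longest first (ties broken by id); each joins
    the first existing representative with global identity >= the
    threshold, else founds a new cluster. Identity is matches / alignment
    columns of a global alignment; a member shorter than
    ``identity * len(representative)`` cannot reach the threshold and is
    skipped without aligning.
    """
    if not (0.0 < identity <= 1.0):
        raise ValueError("identity must be in (0, 1]")
    order = sorted(transcripts, key=lambda r: (-len(r[1]), r[0]))
    clusters: list[Cluster] = []
    reps: list[tuple[str, str]] = []
    for tid, seq in order:
        joined = False
        for ci, (rid, rseq) in enumerate(reps):
            if len(seq) < identity * len(rseq):
                continue
            if global_identity(seq, rseq) >= identity:
                clusters[ci].members.append(tid)
                joined = True
                break
        if not joined:
            reps.append((tid, seq))
            clusters.append(Cluster(representative=tid, members=[tid]))
    return clusters


# ---------------------------------------------------------------------------
# Contaminant screen
# ---------------------------------------------------------------------------

def flag_contaminants(
    transcripts: list[tuple[str, str]],
    contaminant_refs: list[tuple[str, str]],
    min_coverage: float = 0.50,
    min_identity: float = 0.90,
) -> dict[str, bool]:
    """Flag transcripts whose local alignments to any contaminant
    reference cover >= ``min_coverage`` of the transcript at
    >= ``min_identity``. An empty reference flags nothing."""
    flags = {tid: False for tid, _ in transcripts}
    if not contaminant_refs:
        return flags
    index = KmerIndex(k=12)
    for name, seq in contaminant_refs:
        index.add(name, seq)
    for tid, seq in transcripts:
        blocks = [
            b
            for b in seed_blocks(seq, index=index, min_identity=min_identity, min_len=20)
        ]
        by_ref: dict[str, list[dict]] = {}
        for b in blocks:
            by_ref.setdefault(b["target"], []).append(b)
        for ref_blocks in by_ref.values():
            if covered_fraction(ref_blocks, len(seq)) >= min_coverage:
                flags[tid] = True
                break
    return flags


# ---------------------------------------------------------------------------
# Coding-potential assessment
# ---------------------------------------------------------------------------

def assess_coding(
    sequence: str,
    hexamer_model: HexamerModel | None,
    proteins: list[tuple[str, str]],
    min_orf_codons: int = 100,
    protein_min_score: float = 60.0,
) -> CodingAssessment:
    """Run the three coding predictors on one transcript.

    * ORF predictor: longest ATG..stop ORF (any frame, both strands)
      >= ``min_orf_codons`` codons.
    * Hexamer predictor: mean in-frame hexamer log-odds over the longest
      ORF > 0 (coding-like usage bias).
    * Homology predictor: some six-frame translation has a local
      protein-level alignment scoring >= ``protein_min_score`` against the
      protein set (a cheap shared-peptide-6-mer seed gates the quadratic
      alignment). Empty protein set => False.
    """
    if not sequence:
        raise ValueError("empty sequence")
    ncod, orf_seq = longest_orf(sequence)  # validates the alphabet
    orf_pred = ncod >= min_orf_codons
    hex_pred = bool(orf_seq) and hexamer_model is not None and hexamer_model.score(orf_seq) > 0
    hom_pred = False
    if proteins:
        frames = translate_frames(sequence)
        for _, prot in proteins:
            if not shared_peptide_kmer(frames, prot):
                continue
            if any(protein_local_score(f, prot) >= protein_min_score for f in frames):
                hom_pred = True
                break
    return CodingAssessment(
        orf_predictor=orf_pred,
        hexamer_predictor=hex_pred,
        homology_predictor=hom_pred,
        longest_orf_codons=ncod,
    )


def call_class(
    record: TranscriptRecord, assessment: CodingAssessment, min_len: int = 200
) -> str:
    """Terminal class from the predictor verdicts and the length split:
    coding_predicted if ANY predictor fired, else small_ncRNA below
    ``min_len`` nt, else lncRNA."""
    if assessment.any_coding:
        return "coding_predicted"
    if record.length < min_len:
        return "small_ncRNA"
    return "lncRNA"


# ---------------------------------------------------------------------------
# miRNA precursor scan
# ---------------------------------------------------------------------------

def _hamming_occurrences(text: str, query: str, max_mm: int) -> bool:
    """True iff query occurs in text with <= max_mm mismatches (no gaps)."""
    n, m = len(text), len(query)
    if m > n:
        return False
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mism = (windows != q).sum(axis=1)
    return bool((mism <= max_mm).any())


def flag_mirna_precursors(
    lncrnas: list[tuple[str, str]],
    mature_mirnas: list[tuple[str, str]],
    max_mismatch: int = 1,
) -> dict[str, bool]:
    """Flag lncRNAs containing a mature miRNA (or its reverse complement)
    with at most ``max_mismatch`` mismatches (Hamming, no gaps). Queries
    longer than the lncRNA are skipped for that lncRNA."""
    flags = {tid: False for tid, _ in lncrnas}
    queries = []
    for mid, mseq in mature_mirnas:
        queries.append(mseq)
        queries.append(revcomp(mseq))
    for tid, seq in lncrnas:
        for q in queries:
            if len(q) <= len(seq) and _hamming_occurrences(seq, q, max_mismatch):
                flags[tid] = True
                break
    return flags


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def run_cascade(
    transcripts: list[tuple[str, str]],
    contaminant_refs: list[tuple[str, str]],
    proteins: list[tuple[str, str]],
    mirnas: list[tuple[str, str]],
    coding_ref: list[tuple[str, str]] | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Run the full identification cascade; returns the catalog table.

    Stages: redundancy clustering (representatives continue), contaminant
    screen, protein-database screen (terminal class ``protein_match``),
    coding-potential predictors (``coding_predicted`` when the ORF or
    hexamer predictor fires), the 200-nt length split, then the miRNA
    precursor scan over called lncRNAs. Cluster members inherit the
    ``redundant`` disposition and their representative's id. The terminal
    classes partition the input: every transcript gets exactly one.
    """
    cfg = config or PipelineConfig()
    hexamer_model = (
        HexamerModel.train_from_coding([s for _, s in coding_ref]) if coding_ref else None
    )
    clusters = cluster_redundant(transcripts, cfg.cluster_identity)
    rep_of = {m: c.representative for c in clusters for m in c.members}
    seq_of = dict(transcripts)
    reps = [(c.representative, seq_of[c.representative]) for c in clusters]

    cont_flags = flag_contaminants(
        reps, contaminant_refs, cfg.contaminant_coverage, cfg.contaminant_identity
    )
    rows: dict[str, dict] = {}
    lnc_list: list[tuple[str, str]] = []
    for tid, seq in reps:
        rec = TranscriptRecord(id=tid, sequence=seq)
        if cont_flags[tid]:
            terminal = "contaminant"
            assessment = CodingAssessment(False, False, False, 0)
        else:
            assessment = assess_coding(
                seq,
                hexamer_model,
                proteins,
                cfg.min_orf_codons,
                cfg.protein_min_score,
            )
            if assessment.homology_predictor:
                terminal = "protein_match"
            else:
                terminal = call_class(rec, assessment, cfg.min_lncrna_len)
        if terminal == "lncRNA":
            lnc_list.append((tid, seq))
        rows[tid] = {
            "transcript_id": tid,
            "length": len(seq),
            "cluster_id": tid,
            "redundant": False,
            "terminal_class": terminal,
            "orf_predictor": assessment.orf_predictor,
            "hexamer_predictor": assessment.hexamer_predictor,
            "homology_predictor": assessment.homology_predictor,
            "longest_orf_codons": assessment.longest_orf_codons,
            "mirna_precursor": False,
        }
    mir_flags = flag_mirna_precursors(lnc_list, mirnas, cfg.mirna_max_mismatch)
    for tid, f in mir_flags.items():
        rows[tid]["mirna_precursor"] = f
    for tid, seq in transcripts:
        if tid in rows:
            continue
        rep = rep_of[tid]
        rows[tid] = {
            "transcript_id": tid,
            "length": len(seq),
            "cluster_id": rep,
            "redundant": True,
            "terminal_class": rows[rep]["terminal_class"],
            "orf_predictor": False,
            "hexamer_predictor": False,
            "homology_predictor": False,
            "longest_orf_codons": 0,
            "mirna_precursor": False,
        }
    df = pd.DataFrame(rows.values()).set_index("transcript_id", drop=False)
    return df.loc[[tid for tid, _ in transcripts]]
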