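"""Genomic context of lncRNAs relative to annotated coding genes.

Classifies uniquely mapped lncRNAs as intergenic, totally intronic, or
exon-overlapping; tabulates exon counts; and correlates lncRNA expression
with coding genes lying within a distance window. All overlap logic is
strand-blind because the underlying libraries are not strand-oriented.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .models import CONDITIONS, GenomeAnnotation, TranscriptAlignment


def classify_mapping(
    alignments: list[TranscriptAlignment], transcript_ids: list[str] | None = None
) -> dict[str, str]:
    """Per-transcript mapping status: unmapped / unique / multi.

    ``transcript_ids`` may supply the full universe so that transcripts
    with zero placements are reported as unmapped.
    """
    counts: dict[str, int] = {}
    for a in alignments:
        counts[a.transcript_id] = counts.get(a.transcript_id, 0) + 1
    universe = transcript_ids if transcript_ids is not None else list(counts)
    out = {}
    for tid in universe:
        n = counts.get(tid, 0)
        out[tid] = "unmapped" if n == 0 else ("unique" if n == 1 else "multi")
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_context(
    alignment: TranscriptAlignment, annotation: GenomeAnnotation
) -> tuple[str, bool]:
    """Classify one uniquely mapped transcript.

    Returns (class, spliced): ``exonic_overlap`` if any block intersects
    any exon of any coding gene; else ``intronic`` if the whole transcript
    span lies within a single gene's span (i.e. totally inside introns);
    else ``intergenic``. Strand is ignored.
    """
    if alignment.chrom not in {n for n, _ in annotation.chromosomes}:
        raise ValueError(f"chromosome {alignment.chrom} absent from annotation")
    span = (alignment.start, alignment.end)
    genes = [g for g in annotation.genes_on(alignment.chrom) if g.biotype == "coding"]
    for g in genes:
        if not _overlap(span, g.span):
            continue
        for ex in g.exons:
            if any(_overlap(b, ex) for b in alignment.blocks):
                return "exonic_overlap", alignment.spliced
    for g in genes:
        if g.start <= span[0] and span[1] <= g.end:
            return "intronic", alignment.spliced
    # partial gene overlap without touching an exon (transcript sticking
    # out of a gene through an intron end) is not "totally intronic"
    return "intergenic", alignment.spliced


def exon_count_histogram(alignments: list[TranscriptAlignment]) -> dict:
    """Histogram of blocks per uniquely mapped transcript plus the mean
    exon count among spliced (>= 2 blocks) transcripts; the mean is None
    when every transcript is single-block."""
    hist: dict[int, int] = {}
    spliced_counts = []
    for a in alignments:
        n = len(a.blocks)
        hist[n] = hist.get(n, 0) + 1
        if n >= 2:
            spliced_counts.append(n)
    mean_spliced = float(np.mean(spliced_counts)) if spliced_counts else None
    return {"histogram": dict(sorted(hist.items())), "mean_exons_spliced": mean_spliced}


def interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap."""
    return max(0, max(a[0] - b[1], b[0] - a[1]))


def neighbor_correlations(
    lnc_alignments: list[TranscriptAlignment],
    annotation: GenomeAnnotation,
    lnc_fpkm: pd.DataFrame,
    gene_fpkm: pd.DataFrame,
    window: int = 10_000,
) -> pd.DataFrame:
    """Pearson correlation between each lncRNA and coding genes within
    ``window`` bp (gap between spans; overlap counts as gap 0).

    FPKM tables are indexed by lncRNA / gene id with the six condition
    columns. Correlation bins: ``negative`` (r <= -0.01, with a
    ``strong`` flag at r <= -0.5), ``none`` (|r| < 0.01 or undefined from
    zero variance), ``positive`` (r >= 0.01, strong at r >= 0.5).
    """
    for df in (lnc_fpkm, gene_fpkm):
        if list(df.columns) != list(CONDITIONS):
            raise ValueError("FPKM tables must have the six condition columns")
    rows = []
    genes_by_chrom: dict[str, list] = {}
    for g in annotation.genes:
        if g.biotype == "coding":
            genes_by_chrom.setdefault(g.chrom, []).append(g)
    for a in lnc_alignments:
        if a.transcript_id not in lnc_fpkm.index:
            continue
        x = lnc_fpkm.loc[a.transcript_id].to_numpy(dtype=float)
        for g in genes_by_chrom.get(a.chrom, []):
            gap = interval_gap((a.start, a.end), g.span)
            if gap > window:
                continue
            if g.gene_id not in gene_fpkm.index:
                continue
            y = gene_fpkm.loc[g.gene_id].to_numpy(dtype=float)
            r = _pearson(x, y)
            if r is None or abs(r) < 0.01:
                bin_, strong = "none", False
            elif r < 0:
                bin_, strong = "negative", r <= -0.5
            else:
                bin_, strong = "positive", r >= 0.5
            rows.append(
                {
                    "lnc_id": a.transcript_id,
                    "gene_id": g.gene_id,
                    "gap_bp": gap,
                    "r": float("nan") if r is None else r,
                    "bin": bin_,
                    "strong": strong,
                }
            )
    return pd.DataFrame(
        rows, columns=["lnc_id", "gene_id", "gap_bp", "r", "bin", "strong"]
    )


def _pearson(x: np.ndarray, y: np.ndarray):
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need vectors of equal length over >=2 conditions")
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return r if math.isfinite(r) else None


def context_table(
    alignments: list[TranscriptAlignment],
    annotation: GenomeAnnotation,
    transcript_ids: list[str],
) -> pd.DataFrame:
    """Mapping status and genomic class for every transcript id."""
    status = classify_mapping(alignments, transcript_ids)
    by_id: dict[str, TranscriptAlignment] = {}
    for a in alignments:
        by_id.setdefault(a.transcript_id, a)
    rows = []
    for tid in transcript_ids:
        klass, spliced = "", False
        if status[tid] == "unique":
            klass, spliced = classify_context(by_id[tid], annotation)
        rows.append(
            {
                "transcript_id": tid,
                "mapping": status[tid],
                "genomic_class": klass,
                "spliced": spliced,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id", drop=False)
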