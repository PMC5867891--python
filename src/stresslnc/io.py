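"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Bio.SeqIO, GFF3 through gffutils (in-memory DB),
tabular files through pandas. Internally all coordinates are 0-based
half-open; GFF3 files are 1-based inclusive and BED files 0-based
half-open, and the conversion happens here and only here.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CONDITIONS,
    FormatError,
    GeneModel,
    GenomeAnnotation,
    TranscriptAlignment,
)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs.

    Sequences are uppercased and U is converted to T. Duplicate record ids
    are a format error; an empty file yields an empty list.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read gene/exon features from GFF3 into a GenomeAnnotation.

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open. A gene without exon children gets a single exon equal to
    its span. An exon outside its parent gene's span, or any feature with
    end < start, is a format error. Chromosome lengths come from
    ``##sequence-region`` pragmas when present, else from the maximum
    feature end per chromosome.
    """
    text = Path(path).read_text()
    chrom_sizes: dict[str, int] = {}
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                chrom_sizes[parts[1]] = int(parts[3])
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            force=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted internals
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc

    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene", order_by="start"):
        if gf.end < gf.start:
            raise FormatError(f"gene {gf.id}: end < start")
        gs, ge = gf.start - 1, gf.end  # to 0-based half-open
        exons = []
        for ef in db.children(gf, featuretype="exon", order_by="start"):
            if ef.end < ef.start:
                raise FormatError(f"exon of {gf.id}: end < start")
            es, ee = ef.start - 1, ef.end
            if es < gs or ee > ge:
                raise FormatError(
                    f"exon ({ef.start},{ef.end}) outside gene {gf.id} span"
                )
            exons.append((es, ee))
        if not exons:
            exons = [(gs, ge)]
        biotype = gf.attributes.get("biotype", ["coding"])[0]
        strand = gf.strand if gf.strand in ("+", "-") else "unknown"
        genes.append(
            GeneModel(
                gene_id=gf.id,
                chrom=gf.seqid,
                strand=strand,
                exons=sorted(exons),
                biotype=biotype,
            )
        )
        chrom_sizes.setdefault(gf.seqid, 0)
        chrom_sizes[gf.seqid] = max(chrom_sizes[gf.seqid], ge)
    return GenomeAnnotation(
        chromosomes=sorted(chrom_sizes.items()), genes=genes
    )


def write_gff3(path: str | Path, annotation: GenomeAnnotation) -> None:
    """Emit the annotation as GFF3 (1-based inclusive coordinates)."""
    buf = _io.StringIO()
    buf.write("##gff-version 3\n")
    for name, length in annotation.chromosomes:
        buf.write(f"##sequence-region {name} 1 {length}\n")
    for g in annotation.genes:
        strand = g.strand if g.strand in ("+", "-") else "."
        buf.write(
            f"{g.chrom}\tstresslnc\tgene\t{g.start + 1}\t{g.end}\t.\t{strand}\t."
            f"\tID={g.gene_id};biotype={g.biotype}\n"
        )
        for i, (s, e) in enumerate(g.exons, start=1):
            buf.write(
                f"{g.chrom}\tstresslnc\texon\t{s + 1}\t{e}\t.\t{strand}\t."
                f"\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
            )
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# BED12 transcript alignments
# ---------------------------------------------------------------------------

def read_bed12(path: str | Path) -> list[TranscriptAlignment]:
    """Read BED12 alignment lines (one line per genomic placement)."""
    alignments: list[TranscriptAlignment] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise FormatError(f"{path}:{lineno}: expected 12 BED columns")
        chrom, start = f[0], int(f[1])
        name, strand = f[3], f[5]
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise FormatError(f"{path}:{lineno}: blockCount mismatch")
        blocks = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
        if blocks[-1][1] != int(f[2]):
            raise FormatError(f"{path}:{lineno}: blocks do not end at chromEnd")
        alignments.append(
            TranscriptAlignment(
                transcript_id=name,
                chrom=chrom,
                blocks=blocks,
                strand=strand if strand in ("+", "-") else "unknown",
            )
        )
    return alignments


def write_bed12(path: str | Path, alignments: list[TranscriptAlignment]) -> None:
    lines = []
    for a in alignments:
        sizes = ",".join(str(e - s) for s, e in a.blocks)
        starts = ",".join(str(s - a.start) for s, e in a.blocks)
        strand = a.strand if a.strand in ("+", "-") else "."
        lines.append(
            "\t".join(
                [
                    a.chrom,
                    str(a.start),
                    str(a.end),
                    a.transcript_id,
                    "0",
                    strand,
                    str(a.start),
                    str(a.end),
                    "0",
                    str(len(a.blocks)),
                    sizes,
                    starts,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Count matrix and other tables
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read the 6-condition count matrix (transcripts x conditions).

    The first column holds transcript ids; the six condition columns must
    be exactly the leaf/root x control/3h/96h labels. Counts must be
    non-negative integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    expected = list(CONDITIONS)
    if list(df.columns) != expected:
        raise FormatError(
            f"count matrix columns {list(df.columns)} != expected {expected}"
        )
    if df.isna().any().any():
        raise FormatError("count matrix contains missing values")
    values = df.to_numpy()
    if (values < 0).any():
        raise FormatError("negative count in matrix")
    if not (values == values.astype(int)).all():
        raise FormatError("non-integer count in matrix")
    return df.astype(int)


def write_counts(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="transcript_id")


def read_go_map(path: str | Path) -> pd.DataFrame:
    """Read gene -> GO term annotation (gene, term, namespace[, name])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "term", "namespace"}
    if not required.issubset(df.columns):
        raise FormatError(f"go map needs columns {sorted(required)}")
    if "name" not in df.columns:
        df["name"] = df["term"]
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table (target, sample, replicate columns, ct)."""
    df = pd.read_csv(path, sep="\t")
    required = {"target", "tissue", "time", "bio_rep", "tech_rep", "ct"}
    if not required.issubset(df.columns):
        raise FormatError(f"ct table needs columns {sorted(required)}")
    if (df["ct"] <= 0).any():
        raise FormatError("Ct values must be positive")
    return df
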