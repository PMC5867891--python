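"""Core domain types shared across the pipeline.

All genomic intervals are stored 0-based, half-open. Conversion to the
1-based inclusive GFF3 convention (and back) happens only at format
boundaries in :mod:`stresslnc.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

CONDITIONS = (
    "leaf_control",
    "leaf_3h",
    "leaf_96h",
    "root_control",
    "root_3h",
    "root_96h",
)

TISSUES = ("leaf", "root")
CONTRASTS = ("3h_vs_control", "96h_vs_control")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GeneModel:
    """An annotated gene: exon blocks on one chromosome.

    Exons are 0-based half-open intervals, sorted and disjoint. Because the
    sequencing libraries this pipeline targets are not strand-oriented, the
    strand of discovered transcripts is usually ``"unknown"``; annotated
    coding genes carry ``"+"`` or ``"-"``.
    """

    gene_id: str
    chrom: str
    strand: str  # "+", "-", or "unknown"
    exons: list[tuple[int, int]]
    biotype: str = "coding"  # "coding" or "lncRNA"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus the gene models annotated on them."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        sizes = dict(self.chromosomes)
        for g in self.genes:
            if g.chrom not in sizes:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > sizes[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id}: span ({g.start},{g.end}) outside "
                    f"{g.chrom} (len {sizes[g.chrom]})"
                )

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]

    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "coding"]


# Terminal classes of the identification cascade, mutually exclusive.
TERMINAL_CLASSES = (
    "contaminant",
    "protein_match",
    "coding_predicted",
    "small_ncRNA",
    "lncRNA",
)


@dataclass
class TranscriptRecord:
    """One assembled transcript with provenance and cascade flags."""

    id: str
    sequence: str
    source: str = "denovo"  # "denovo" or "genome_based"
    terminal_class: Optional[str] = None
    mirna_precursor: bool = False
    cluster_id: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CodingAssessment:
    """Verdicts of the three coding-potential predictors for one transcript."""

    orf_predictor: bool
    hexamer_predictor: bool
    homology_predictor: bool
    longest_orf_codons: int

    @property
    def any_coding(self) -> bool:
        return self.orf_predictor or self.hexamer_predictor or self.homology_predictor


@dataclass
class TranscriptAlignment:
    """One genomic placement of a transcript (BED12-style exon blocks)."""

    transcript_id: str
    chrom: str
    blocks: list[tuple[int, int]]
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"{self.transcript_id}: alignment needs >=1 block")
        prev = -1
        for s, e in self.blocks:
            if e <= s or s < prev:
                raise ValueError(f"{self.transcript_id}: bad blocks {self.blocks}")
            prev = e

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def spliced(self) -> bool:
        return len(self.blocks) >= 2


@dataclass
class TransNATPair:
    """A trans natural antisense candidate pair.

    Pairing blocks are stored per member as 0-based half-open intervals on
    that member's own sequence; ``longest_run`` is the longest single
    continuous paired block in nucleotides.
    """

    query_id: str  # lncRNA
    target_id: str
    target_type: str  # "coding" or "lncRNA"
    query_blocks: list[tuple[int, int]]
    target_blocks: list[tuple[int, int]]
    longest_run: int
    coverage_query: float
    coverage_target: float
    pair_class: Optional[str] = None  # "high_coverage", "nt100", or None

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.query_id, self.target_id)))


@dataclass
class DERecord:
    """Differential-expression call for one transcript in one contrast."""

    transcript_id: str
    tissue: str
    contrast: str
    log2fc: float
    p_value: float
    is_de: bool
    response_class: str = "none"


@dataclass
class StructureZScore:
    """Folding-stability z-score of one transcript vs shuffled nulls."""

    transcript_id: str
    native_energy: float
    null_mean: float
    null_sd: float
    z: Optional[float]
    n_shuffles: int
    degenerate: bool = False


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    k_in_set: int
    K_in_background: int
    n_set: int
    N_background: int
    p_value: float
    enriched: bool
    p_adjusted: Optional[float] = None
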