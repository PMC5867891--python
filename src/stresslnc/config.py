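"""Pipeline configuration: every tunable threshold in one place.

Defaults follow the analysis protocol this pipeline reproduces: 90% global
identity for redundancy clustering, 200 nt minimum lncRNA length, 1 FPKM
expressed cutoff, 4-fold / p<0.001 differential-expression calls, 100 nt
minimum continuous pairing run for trans-NAT "100 nt" pairs, 10 kb neighbor
window, 75% mutual coverage / 90% identity for transcript-set conservation
and 90% coverage for genomic conservation. Cutoffs the protocol leaves
unstated (ORF codon threshold, contaminant screen coverage, pairing block
identity, protein alignment score) are exposed here with documented
defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # catalog
    cluster_identity: float = 0.90
    contaminant_coverage: float = 0.50
    contaminant_identity: float = 0.90
    min_lncrna_len: int = 200
    min_orf_codons: int = 100
    protein_min_score: float = 60.0  # Smith-Waterman BLOSUM62 score cutoff
    mirna_max_mismatch: int = 1
    # conservation
    genome_coverage: float = 0.90
    genome_identity: float = 0.90
    mutual_coverage: float = 0.75
    set_identity: float = 0.90
    read_support_coverage: float = 0.80
    # expression / DE
    expressed_fpkm: float = 1.0
    fold_cutoff: float = 4.0
    p_cutoff: float = 0.001
    dispersion: float = 0.1
    pseudo_count: float = 0.5
    tmm_trim_m: float = 0.30
    tmm_trim_a: float = 0.05
    # genomic context
    neighbor_window: int = 10_000
    # trans-NAT
    nat_min_run: int = 100
    nat_min_identity: float = 0.80
    nat_high_coverage: float = 0.50
    nat_both_members: bool = True  # coverage rule applies to both members
    ratio_epsilon: float = 0.01
    # structure
    n_shuffles: int = 30
    # enrichment
    enrich_alpha: float = 0.05
    enrich_fdr: bool = False
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cluster_identity",
            "contaminant_coverage",
            "contaminant_identity",
            "genome_coverage",
            "genome_identity",
            "mutual_coverage",
            "set_identity",
            "read_support_coverage",
            "nat_min_identity",
            "nat_high_coverage",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in (
            "min_lncrna_len",
            "min_orf_codons",
            "expressed_fpkm",
            "fold_cutoff",
            "p_cutoff",
            "neighbor_window",
            "nat_min_run",
            "n_shuffles",
            "pseudo_count",
            "ratio_epsilon",
            "enrich_alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def digest(self) -> str:
        """Short hash of the full configuration, for run logging."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
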