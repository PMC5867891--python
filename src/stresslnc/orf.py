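"""Open-reading-frame scanning and the hexamer coding-bias model.

An ORF here is ATG..stop in any of the six frames (both strands, three
frames each); its length is counted in codons including the stop codon.
The hexamer model scores the in-frame hexamer composition of an ORF
against coding vs background frequency tables, the classic usage-bias
signal behind coding-potential classifiers.
"""

from __future__ import annotations

import math

import numpy as np

from .align import revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")

_VALID = set("ACGTN")


def _orfs_in_frame(s: str, frame: int):
    """Yield (start, n_codons) of ATG..stop ORFs in one frame of one strand."""
    open_start = None
    for i in range(frame, len(s) - 2, 3):
        codon = s[i : i + 3]
        if codon in STOP_CODONS:
            if open_start is not None:
                yield open_start, (i + 3 - open_start) // 3
                open_start = None
        elif codon == "ATG" and open_start is None:
            open_start = i


def longest_orf(seq: str) -> tuple[int, str]:
    """Longest ATG..stop ORF over both strands; returns (codons, orf_seq).

    The codon count includes the stop codon. Returns (0, "") when no
    complete ORF exists. Raises on symbols outside ACGTN.
    """
    if set(seq) - _VALID:
        raise ValueError(f"non-ACGTN symbol in sequence: {sorted(set(seq) - _VALID)}")
    best = (0, "")
    for s in (seq, revcomp(seq)):
        for frame in range(3):
            for start, ncod in _orfs_in_frame(s, frame):
                if ncod > best[0]:
                    best = (ncod, s[start : start + 3 * ncod])
    return best


class HexamerModel:
    """In-frame hexamer log-odds table (coding vs background)."""

    def __init__(self, log_odds: dict[str, float]):
        self.log_odds = log_odds

    @classmethod
    def train(cls, coding_orfs: list[str], background_seqs: list[str]) -> "HexamerModel":
        """Train from in-frame hexamers of coding ORFs vs background hexamers.

        Both tables use step-3 (codon-aligned) hexamers and Laplace
        smoothing; the background is typically shuffled coding sequence,
        so the score isolates ordering (usage bias), not base composition.
        """
        def table(seqs):
            counts: dict[str, int] = {}
            for s in seqs:
                for i in range(0, len(s) - 5, 3):
                    h = s[i : i + 6]
                    if "N" not in h:
                        counts[h] = counts.get(h, 0) + 1
            total = sum(counts.values()) + 4096
            return counts, total

        cod, cod_total = table(coding_orfs)
        bg, bg_total = table(background_seqs)
        log_odds = {}
        for i in range(4096):
            h = "".join("ACGT"[(i >> (2 * j)) & 3] for j in range(5, -1, -1))
            p_c = (cod.get(h, 0) + 1) / cod_total
            p_b = (bg.get(h, 0) + 1) / bg_total
            log_odds[h] = math.log(p_c / p_b)
        return cls(log_odds)

    @classmethod
    def train_from_coding(
        cls, coding_mrnas: list[str], rng: np.random.Generator | int = 0
    ) -> "HexamerModel":
        """Convenience trainer: ORFs of the given coding transcripts vs
        mononucleotide-shuffled copies of the same ORFs."""
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        orfs = []
        for m in coding_mrnas:
            _, orf = longest_orf(m)
            if orf:
                orfs.append(orf)
        shuffled = []
        for orf in orfs:
            arr = np.frombuffer(orf.encode(), dtype=np.uint8).copy()
            rng.shuffle(arr)
            shuffled.append(arr.tobytes().decode())
        return cls.train(orfs, shuffled)

    def score(self, orf_seq: str) -> float:
        """Mean in-frame hexamer log-odds over an ORF; 0.0 if too short."""
        vals = [
            self.log_odds[orf_seq[i : i + 6]]
            for i in range(0, len(orf_seq) - 5, 3)
            if "N" not in orf_seq[i : i + 6]
        ]
        return float(np.mean(vals)) if vals else 0.0
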