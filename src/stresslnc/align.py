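"""Sequence-alignment primitives shared across pipeline stages.

Two workhorses live here:

* :func:`global_identity` — global (Needleman-Wunsch) percent identity via
  edlib's edit-distance alignment, used by redundancy clustering. Identity
  is matches / alignment-columns; ``N`` never counts as a match.
* :func:`seed_blocks` — a gapless seed-and-merge local similarity search:
  exact k-mer seeds between query and target are grouped by diagonal and
  merged into maximal blocks whose internal identity is computed by direct
  (Hamming) comparison. This is the internal stand-in for the BLASTn/BLAT
  searches of the original protocol; it recovers co-linear, substitution-
  diverged homology, which is exactly what the contaminant screen,
  conservation scan and antisense pairing stages need at toy scale.

Protein-level homology (the BLASTx stand-in) goes through biotite's
C-accelerated Smith-Waterman with BLOSUM62.
"""

from __future__ import annotations

import re
from typing import Iterable

import edlib
import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def global_identity(a: str, b: str) -> float:
    """Global alignment identity: matches / alignment length.

    Columns where either base is ``N`` are never counted as matches but do
    count toward the alignment length.
    """
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    total = 0
    ai = bi = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        total += n
        if op in ("=", "M"):
            for k in range(n):
                ca, cb = a[ai + k], b[bi + k]
                if ca == cb and ca != "N":
                    matches += 1
            ai += n
            bi += n
        elif op == "X":
            ai += n
            bi += n
        elif op == "I":  # in query a
            ai += n
        elif op == "D":
            bi += n
    return matches / total if total else 0.0


class KmerIndex:
    """Exact k-mer position index over one or more target sequences."""

    def __init__(self, k: int = 12):
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        self.lengths: dict[str, int] = {}
        self.seqs: dict[str, str] = {}

    def add(self, name: str, seq: str) -> None:
        k = self.k
        self.lengths[name] = len(seq)
        self.seqs[name] = seq
        idx = self._index
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            idx.setdefault(kmer, []).append((name, i))

    def seeds(self, query: str) -> dict[str, list[tuple[int, int]]]:
        """Map target name -> list of (query_pos, target_pos) seed hits."""
        k = self.k
        out: dict[str, list[tuple[int, int]]] = {}
        idx = self._index
        for i in range(len(query) - k + 1):
            hits = idx.get(query[i : i + k])
            if not hits:
                continue
            for name, j in hits:
                out.setdefault(name, []).append((i, j))
        return out


def _merge_diagonal_runs(
    positions: list[tuple[int, int]], k: int, max_gap: int
) -> list[tuple[int, int]]:
    """Merge co-diagonal seed hits into (qstart, qend) runs on the query."""
    runs: list[tuple[int, int]] = []
    start, end = positions[0][0], positions[0][0] + k
    for q, _ in positions[1:]:
        if q <= end + max_gap:
            end = max(end, q + k)
        else:
            runs.append((start, end))
            start, end = q, q + k
    runs.append((start, end))
    return runs


def seed_blocks(
    query: str,
    target: str | None = None,
    *,
    index: KmerIndex | None = None,
    k: int = 12,
    max_gap: int = 30,
    min_identity: float = 0.0,
    min_len: int = 0,
) -> list[dict]:
    """Find gapless local similarity blocks between query and target(s).

    Returns a list of block dicts with keys ``target``, ``qstart``,
    ``qend``, ``tstart``, ``tend``, ``identity``, ``length``. Blocks are
    maximal co-diagonal runs of exact k-mer seeds, merged across gaps of up
    to ``max_gap`` columns; identity inside a merged block is the Hamming
    identity of the two subsequences (``N`` never matches).
    """
    if index is None:
        if target is None:
            raise ValueError("need a target or an index")
        index = KmerIndex(k=k)
        index.add("target", target)
    blocks: list[dict] = []
    for name, hits in index.seeds(query).items():
        bydiag: dict[int, list[tuple[int, int]]] = {}
        for q, t in hits:
            bydiag.setdefault(t - q, []).append((q, t))
        tseq = index.seqs[name]
        for diag, positions in bydiag.items():
            positions.sort()
            for qs, qe in _merge_diagonal_runs(positions, index.k, max_gap):
                ts, te = qs + diag, qe + diag
                qsub = query[qs:qe]
                tsub = tseq[ts:te]
                ident = hamming_identity(qsub, tsub)
                if qe - qs >= min_len and ident >= min_identity:
                    blocks.append(
                        {
                            "target": name,
                            "qstart": qs,
                            "qend": qe,
                            "tstart": ts,
                            "tend": te,
                            "identity": ident,
                            "length": qe - qs,
                        }
                    )
    return blocks


def hamming_identity(a: str, b: str) -> float:
    """Identity of two equal-length strings; N never counts as a match."""
    if len(a) != len(b):
        raise ValueError("hamming_identity needs equal lengths")
    if not a:
        return 0.0
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    n_code = ord("N")
    matches = int(np.sum((aa == bb) & (aa != n_code)))
    return matches / len(a)


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def covered_fraction(blocks: list[dict], length: int, side: str = "q") -> float:
    """Fraction of the query (or target) covered by the union of blocks."""
    if length <= 0:
        return 0.0
    key_s, key_e = (f"{side}start", f"{side}end")
    return union_length((b[key_s], b[key_e]) for b in blocks) / length


# ---------------------------------------------------------------------------
# Protein-level local alignment (BLASTx stand-in)
# ---------------------------------------------------------------------------

_CODON_TABLE = None


def translate_frames(seq: str) -> list[str]:
    """Six-frame translation; stops appear as '*'."""
    from Bio.Seq import Seq

    out = []
    for s in (seq, revcomp(seq)):
        for f in range(3):
            sub = s[f : f + 3 * ((len(s) - f) // 3)]
            if len(sub) >= 3:
                out.append(str(Seq(sub).translate()))
    return out


_BLOSUM = None


def _blosum():
    global _BLOSUM
    if _BLOSUM is None:
        from biotite.sequence.align import SubstitutionMatrix

        _BLOSUM = SubstitutionMatrix.std_protein_matrix()
    return _BLOSUM


def protein_local_score(pep_a: str, pep_b: str) -> float:
    """Best Smith-Waterman score (BLOSUM62, gap open -11 / extend -1)."""
    from biotite.sequence import ProteinSequence
    from biotite.sequence.align import align_optimal

    # strip stops and ambiguous residues biotite cannot represent
    clean = lambda p: re.sub(r"[^ACDEFGHIKLMNPQRSTVWY]", "", p)
    a, b = clean(pep_a), clean(pep_b)
    if not a or not b:
        return 0.0
    alns = align_optimal(
        ProteinSequence(a),
        ProteinSequence(b),
        _blosum(),
        gap_penalty=(-11, -1),
        local=True,
        max_number=1,
    )
    return float(alns[0].score) if alns else 0.0


def shared_peptide_kmer(pep_frames: list[str], protein: str, k: int = 6) -> bool:
    """Cheap seed filter: does any frame share a peptide k-mer with protein?"""
    kmers = set()
    for frame in pep_frames:
        for part in frame.split("*"):
            for i in range(len(part) - k + 1):
                kmers.add(part[i : i + k])
    return any(protein[i : i + k] in kmers for i in range(len(protein) - k + 1))
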