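"""Folding-stability z-scores against dinucleotide-preserving shuffles.

The folding score is a deliberately simple minimum-"energy" proxy: a
Nussinov-style dynamic program over canonical pairs with pair weights
GC = -3, AU = -2, GU = -1 and a minimum hairpin loop of 3 unpaired
bases; the score of a structure is the sum of its pair weights and the
reported energy is the optimum (always <= 0). The z-score compares the
native score with the score distribution over dinucleotide-preserving
shuffles (Altschul-Erikson), so a strongly negative z indicates folding
stability beyond what base and dinucleotide composition explain.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .models import StructureZScore

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair weights, symmetric; index 4 is a non-pairing code for N/unknowns;
# min hairpin loop of 3 => j - i >= 4
_PAIR_W = np.zeros((5, 5), dtype=np.int64)
for _a, _b, _w in (("G", "C", -3), ("A", "T", -2), ("G", "T", -1)):
    _PAIR_W[_CODE[_a], _CODE[_b]] = _w
    _PAIR_W[_CODE[_b], _CODE[_a]] = _w

MIN_LOOP = 3


@njit(cache=True)
def _nussinov(codes: np.ndarray, pair_w: np.ndarray, min_loop: int) -> float:
    n = codes.shape[0]
    E = np.zeros((n, n), dtype=np.int64)
    for l in range(1, n):
        for i in range(0, n - l):
            j = i + l
            best = E[i + 1, j]
            if E[i, j - 1] < best:
                best = E[i, j - 1]
            if l > min_loop:
                w = pair_w[codes[i], codes[j]]
                if w < 0 and E[i + 1, j - 1] + w < best:
                    best = E[i + 1, j - 1] + w
            for k in range(i + 1, j):
                cand = E[i, k] + E[k + 1, j]
                if cand < best:
                    best = cand
            E[i, j] = best
    return float(E[0, n - 1])


def fold_energy(sequence: str, min_len: int = 20) -> float:
    """Minimum pair-sum score of any nested canonical structure.

    Always <= 0 (the empty structure scores 0). Sequences shorter than
    ``min_len`` are rejected; unknown symbols (including N) cannot pair.
    """
    if len(sequence) < min_len:
        raise ValueError(f"sequence shorter than {min_len} nt")
    codes = np.array([_CODE.get(c, 4) for c in sequence.upper()], dtype=np.int64)
    return _nussinov(codes, _PAIR_W, MIN_LOOP)


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Altschul-Erikson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Random sequence with exactly the original dinucleotide counts.

    Implements the Euler-path shuffle: the sequence is a walk on the
    letter multigraph; a random spanning arborescence toward the final
    letter fixes each letter's last outgoing edge, the remaining edges are
    permuted, and the walk is rebuilt.
    """
    if len(sequence) < 2:
        return sequence
    letters = sorted(set(sequence))
    edges: dict[str, list[str]] = {c: [] for c in letters}
    for a, b in zip(sequence, sequence[1:]):
        edges[a].append(b)
    last = sequence[-1]
    non_final = [c for c in letters if c != last and edges[c]]
    for _ in range(10_000):
        last_edge = {}
        for c in non_final:
            last_edge[c] = edges[c][int(rng.integers(len(edges[c])))]
        # the chosen last edges must lead every letter to the final one
        ok = True
        for c in non_final:
            seen = set()
            cur = c
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("dinucleotide shuffle failed to find an arborescence")
    shuffled_edges = {}
    for c in letters:
        rest = list(edges[c])
        if c in last_edge:
            rest.remove(last_edge[c])
        perm = list(rng.permutation(len(rest)))
        rest = [rest[i] for i in perm]
        if c in last_edge:
            rest.append(last_edge[c])
        shuffled_edges[c] = rest
    out = [sequence[0]]
    ptr = {c: 0 for c in letters}
    cur = sequence[0]
    for _ in range(len(sequence) - 1):
        nxt = shuffled_edges[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def structure_zscore(
    sequence: str,
    n_shuffles: int = 30,
    seed: int | np.random.Generator = 0,
    transcript_id: str = "",
) -> StructureZScore:
    """Z-score of the native folding score against shuffled nulls.

    z = (native - null mean) / null sd (sample sd); if the null scores
    have zero variance the record is flagged degenerate and z is None.
    Deterministic for a fixed seed.
    """
    if n_shuffles < 20:
        raise ValueError("need at least 20 shuffles")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    native = fold_energy(sequence)
    nulls = np.array(
        [fold_energy(dinucleotide_shuffle(sequence, rng)) for _ in range(n_shuffles)]
    )
    mean, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    if sd == 0:
        return StructureZScore(
            transcript_id, native, mean, sd, None, n_shuffles, degenerate=True
        )
    return StructureZScore(
        transcript_id, native, mean, sd, (native - mean) / sd, n_shuffles
    )
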