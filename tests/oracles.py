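"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: quadratic scans, full dynamic
programs, exhaustive enumeration. Nothing imports the code paths it
checks (beyond shared trivial helpers like reverse complement).
"""

from __future__ import annotations

import numpy as np

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


# ---------------------------------------------------------------------------
# Smith-Waterman local alignment (match +1 / mismatch -1 / gap -2)
# ---------------------------------------------------------------------------

def sw_local(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Best local alignment; returns (score, a_span, b_span) with spans
    half-open on each sequence."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=int)
    best, best_pos = 0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
            if H[i, j] > best:
                best, best_pos = H[i, j], (i, j)
    # traceback
    i, j = best_pos
    ai, bj = i, j
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return int(best), (i, ai), (j, bj)


# ---------------------------------------------------------------------------
# Greedy clustering oracle (same scorer, naive loop)
# ---------------------------------------------------------------------------

def greedy_clusters(records, identity, scorer):
    """Longest-first greedy clustering without any shortcuts; ``scorer``
    is the global-identity function under test's own contract."""
    order = sorted(records, key=lambda r: (-len(r[1]), r[0]))
    reps, clusters = [], []
    for tid, seq in order:
        for k, (rid, rseq) in enumerate(reps):
            if scorer(seq, rseq) >= identity:
                clusters[k].append(tid)
                break
        else:
            reps.append((tid, seq))
            clusters.append([tid])
    return [set(c) for c in clusters]


# ---------------------------------------------------------------------------
# Exhaustive nested-structure enumeration for the fold score
# ---------------------------------------------------------------------------

_PAIRS = {("G", "C"): -3, ("C", "G"): -3, ("A", "T"): -2, ("T", "A"): -2,
          ("G", "T"): -1, ("T", "G"): -1}


def fold_brute(seq: str, min_loop: int = 3) -> int:
    """Optimal pair-sum score by recursive enumeration (exponential)."""

    def best(i: int, j: int) -> int:
        if j - i < 1:
            return 0
        # i unpaired
        score = best(i + 1, j)
        # i paired with some k
        for k in range(i + min_loop + 1, j + 1):
            w = _PAIRS.get((seq[i], seq[k]))
            if w is not None:
                score = min(score, w + best(i + 1, k - 1) + best(k + 1, j))
        return score

    return best(0, len(seq) - 1)


# ---------------------------------------------------------------------------
# Hamming sliding-window miRNA scan
# ---------------------------------------------------------------------------

def mirna_scan(lnc: str, mirnas: list[str], max_mm: int) -> bool:
    for q in mirnas:
        for query in (q, revcomp(q)):
            if len(query) > len(lnc):
                continue
            for i in range(len(lnc) - len(query) + 1):
                mm = sum(1 for a, b in zip(lnc[i : i + len(query)], query) if a != b)
                if mm <= max_mm:
                    return True
    return False


# ---------------------------------------------------------------------------
# Per-base genomic overlap oracle
# ---------------------------------------------------------------------------

def context_per_base(blocks, span, genes) -> str:
    """Classify by literal per-base membership tests.

    ``genes`` is a list of (gene_span, exon_list). Exonic overlap if any
    transcript-block base lies inside any exon; else intronic if every
    base of the transcript span lies inside one gene's span; else
    intergenic.
    """
    tx_bases = {p for s, e in blocks for p in range(s, e)}
    for (gs, ge), exons in genes:
        exon_bases = {p for s, e in exons for p in range(s, e)}
        if tx_bases & exon_bases:
            return "exonic_overlap"
    for (gs, ge), exons in genes:
        if all(gs <= p < ge for p in range(span[0], span[1])):
            return "intronic"
    return "intergenic"


# ---------------------------------------------------------------------------
# Binomial exact test by full enumeration
# ---------------------------------------------------------------------------

def binomial_two_sided(y1: int, y2: int) -> float:
    """Sum of P(X=k) over all k with P(X=k) <= P(X=y1), X~Bin(y1+y2, 1/2)."""
    from math import comb

    s = y1 + y2
    probs = [comb(s, k) * 0.5**s for k in range(s + 1)]
    obs = probs[y1]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-12)))


# ---------------------------------------------------------------------------
# Trimmed weighted-mean TMM oracle (spreadsheet style)
# ---------------------------------------------------------------------------

def tmm_factor_oracle(obs, ref, trim_m=0.30, trim_a=0.05):
    """TMM factor of obs vs ref, written as an explicit step-by-step
    recipe over a small matrix with all-positive counts."""
    import math

    obs = [float(x) for x in obs]
    ref = [float(x) for x in ref]
    No, Nr = sum(obs), sum(ref)
    rows = []
    for o, r in zip(obs, ref):
        if o <= 0 or r <= 0:
            continue
        m = math.log2((o / No) / (r / Nr))
        a = 0.5 * math.log2((o / No) * (r / Nr))
        w = (No - o) / (No * o) + (Nr - r) / (Nr * r)
        rows.append((m, a, w))
    n = len(rows)
    by_m = sorted(range(n), key=lambda i: rows[i][0])
    by_a = sorted(range(n), key=lambda i: rows[i][1])
    lo_m = int(math.floor(n * trim_m))
    lo_a = int(math.floor(n * trim_a))
    keep_m = set(by_m[lo_m : n - lo_m])
    keep_a = set(by_a[lo_a : n - lo_a])
    keep = keep_m & keep_a
    num = sum(rows[i][0] / rows[i][2] for i in keep)
    den = sum(1.0 / rows[i][2] for i in keep)
    return 2 ** (num / den)


# ---------------------------------------------------------------------------
# Longest exact common substring (full DP)
# ---------------------------------------------------------------------------

def longest_common_substring(a: str, b: str):
    """(length, a_start, b_start) of the longest exact common substring."""
    n, m = len(a), len(b)
    L = np.zeros((n + 1, m + 1), dtype=int)
    best = (0, 0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                L[i, j] = L[i - 1, j - 1] + 1
                if L[i, j] > best[0]:
                    best = (int(L[i, j]), i - int(L[i, j]), j - int(L[i, j]))
    return best
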