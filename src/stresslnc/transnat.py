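"""Trans natural antisense transcript (trans-NAT) discovery and classes.

A trans-NAT candidate is an extended reverse-complement pairing between a
lncRNA and a transcript from a different locus (coding or lncRNA). Each
lncRNA is searched against the reverse complement of every candidate
partner; gapless pairing blocks are merged from exact k-mer seeds. Pair
classes follow the two-rule scheme: ``high_coverage`` when total paired
bases exceed half of BOTH members' lengths, else ``nt100`` when a single
continuous pairing run is longer than 100 nt; everything else is not a
pair. Co-expression categories and lncRNA/coding expression ratios
summarize the functional potential of each pair per condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .align import KmerIndex, revcomp, seed_blocks, union_length
from .models import TransNATPair


def find_pairs(
    lncrnas: list[tuple[str, str]],
    coding: list[tuple[str, str]],
    min_align_len: int = 50,
    min_identity: float = 0.80,
) -> list[TransNATPair]:
    """Raw complementarity alignments of lncRNAs vs all candidate partners.

    Each lncRNA is aligned against the reverse complement of every coding
    transcript and every other lncRNA; self-pairs are excluded and each
    unordered pair is reported once. Pairing blocks shorter than
    ``min_align_len`` or below ``min_identity`` are dropped; pairs without
    any surviving block are not reported. Block coordinates are given on
    each member's own (sense) sequence.
    """
    lnc_ids = {tid for tid, _ in lncrnas}
    targets = [(tid, seq, "coding") for tid, seq in coding] + [
        (tid, seq, "lncRNA") for tid, seq in lncrnas
    ]
    index = KmerIndex(k=12)
    tlen: dict[str, int] = {}
    ttype: dict[str, str] = {}
    for tid, seq, typ in targets:
        index.add(tid, revcomp(seq))
        tlen[tid] = len(seq)
        ttype[tid] = typ
    pairs: dict[tuple[str, str], TransNATPair] = {}
    for qid, qseq in lncrnas:
        blocks = seed_blocks(
            qseq, index=index, min_identity=min_identity, min_len=min_align_len
        )
        by_target: dict[str, list[dict]] = {}
        for b in blocks:
            if b["target"] == qid:
                continue
            by_target.setdefault(b["target"], []).append(b)
        for tid, tblocks in by_target.items():
            key = tuple(sorted((qid, tid)))
            if ttype[tid] == "lncRNA" and key in pairs:
                continue  # unordered lncRNA-lncRNA pair already found
            qblocks = sorted((b["qstart"], b["qend"]) for b in tblocks)
            # target blocks are on the reverse complement; map them back
            # to sense coordinates of the target
            L = tlen[tid]
            tb = sorted((L - b["tend"], L - b["tstart"]) for b in tblocks)
            longest = max(b["qend"] - b["qstart"] for b in tblocks)
            pairs[key if ttype[tid] == "lncRNA" else (qid, tid)] = TransNATPair(
                query_id=qid,
                target_id=tid,
                target_type=ttype[tid],
                query_blocks=qblocks,
                target_blocks=tb,
                longest_run=longest,
                coverage_query=union_length(qblocks) / len(qseq),
                coverage_target=union_length(tb) / L,
            )
    return list(pairs.values())


def classify_pair(
    pair: TransNATPair,
    high_coverage_fraction: float = 0.50,
    min_run: int = 100,
    both_members: bool = True,
) -> str | None:
    """Assign the pair class.

    ``high_coverage`` iff total paired bases exceed
    ``high_coverage_fraction`` of both members (or either, with
    ``both_members=False``); else ``nt100`` iff the longest single run is
    strictly longer than ``min_run``; else None (not a pair).
    """
    covs = (pair.coverage_query, pair.coverage_target)
    cov_ok = (
        min(covs) > high_coverage_fraction
        if both_members
        else max(covs) > high_coverage_fraction
    )
    if cov_ok:
        return "high_coverage"
    if pair.longest_run > min_run:
        return "nt100"
    return None


def classify_pairs(
    pairs: list[TransNATPair],
    high_coverage_fraction: float = 0.50,
    min_run: int = 100,
    both_members: bool = True,
) -> list[TransNATPair]:
    """Keep and label only the pairs that satisfy a class rule."""
    kept = []
    for p in pairs:
        klass = classify_pair(p, high_coverage_fraction, min_run, both_members)
        if klass is not None:
            p.pair_class = klass
            kept.append(p)
    return kept


def coexpression_categories(
    pairs: list[TransNATPair], expressed: pd.DataFrame
) -> pd.DataFrame:
    """Per-pair, per-condition co-expression category.

    ``both`` when the two members are expressed, ``only_lncRNA`` /
    ``only_coding`` when exactly one is (the query slot is the lncRNA,
    the target slot plays the coding role), ``none`` otherwise.
    """
    rows = []
    for p in pairs:
        for member in (p.query_id, p.target_id):
            if member not in expressed.index:
                raise KeyError(f"pair member {member} missing from expression matrix")
        for cond in expressed.columns:
            q = bool(expressed.at[p.query_id, cond])
            t = bool(expressed.at[p.target_id, cond])
            cat = (
                "both"
                if q and t
                else "only_lncRNA" if q else "only_coding" if t else "none"
            )
            rows.append(
                {
                    "query_id": p.query_id,
                    "target_id": p.target_id,
                    "pair_class": p.pair_class,
                    "condition": cond,
                    "category": cat,
                }
            )
    return pd.DataFrame(rows)


def coexpression_table(categories: pd.DataFrame) -> pd.DataFrame:
    """Condition x category counts per pair class (the published-table
    layout: one row per condition, Both/None/Only-coding/Only-lncRNA
    columns within each class)."""
    out = (
        categories.groupby(["pair_class", "condition", "category"])
        .size()
        .unstack(fill_value=0)
        .reset_index()
    )
    for col in ("both", "none", "only_coding", "only_lncRNA"):
        if col not in out.columns:
            out[col] = 0
    return out


def expression_ratio(
    pairs: list[TransNATPair],
    fpkm_table: pd.DataFrame,
    de_lnc_ids: set[str],
    epsilon: float = 0.01,
) -> pd.DataFrame:
    """log2((lncRNA FPKM + eps) / (partner FPKM + eps)) per condition, for
    pairs whose lncRNA is differentially expressed. Positive values mean
    the lncRNA is expressed above its partner."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rows = []
    for p in pairs:
        if p.query_id not in de_lnc_ids:
            continue
        q = fpkm_table.loc[p.query_id].to_numpy(dtype=float)
        t = fpkm_table.loc[p.target_id].to_numpy(dtype=float)
        ratio = np.log2((q + epsilon) / (t + epsilon))
        rows.append(
            {
                "query_id": p.query_id,
                "target_id": p.target_id,
                **{c: ratio[j] for j, c in enumerate(fpkm_table.columns)},
            }
        )
    return pd.DataFrame(rows)


def top_paired(pairs: list[TransNATPair], k: int = 5) -> pd.DataFrame:
    """The k lncRNAs with the most partners (ties broken by id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for p in pairs:
        counts[p.query_id] = counts.get(p.query_id, 0) + 1
        if p.target_type == "lncRNA":
            counts[p.target_id] = counts.get(p.target_id, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return pd.DataFrame(ranked, columns=["lnc_id", "n_pairs"])
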