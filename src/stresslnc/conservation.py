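"""Conservation of lncRNAs across reference sequence sets.

Three reference modes share one decision contract:

* ``genome`` — hit iff local-alignment blocks cover >= 90% of the
  transcript at >= 90% identity (coverage on the transcript only).
* ``transcripts`` — hit iff an alignment covers >= 75% of BOTH the
  transcript and the published transcript at >= 90% identity.
* ``reads`` — hit iff >= 80% of transcript positions are covered by at
  least one mapped read (read-mapping support for unassembled references).

A transcript with no hit in any genome/read reference is "exclusive" to
the assembled landrace.
"""

from __future__ import annotations

import pandas as pd

from .align import KmerIndex, covered_fraction, seed_blocks, union_length


def _blocks_against(index: KmerIndex, seq: str, min_identity: float) -> list[dict]:
    return seed_blocks(seq, index=index, min_identity=min_identity, min_len=25)


def genome_conservation(
    lncrnas: list[tuple[str, str]],
    reference: list[tuple[str, str]],
    min_coverage: float = 0.90,
    min_identity: float = 0.90,
) -> dict[str, bool]:
    """Hit iff the chained local alignments to the reference cover
    >= ``min_coverage`` of the transcript at >= ``min_identity``."""
    if not (0 < min_coverage <= 1 and 0 < min_identity <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    hits = {tid: False for tid, _ in lncrnas}
    if not reference:
        return hits
    index = KmerIndex(k=12)
    for name, seq in reference:
        index.add(name, seq)
    for tid, seq in lncrnas:
        blocks = _blocks_against(index, seq, min_identity)
        if covered_fraction(blocks, len(seq)) >= min_coverage:
            hits[tid] = True
    return hits


def transcript_set_conservation(
    lncrnas: list[tuple[str, str]],
    published: list[tuple[str, str]],
    mutual_coverage: float = 0.75,
    identity: float = 0.90,
) -> dict[str, bool]:
    """Hit iff an alignment to some published transcript covers
    >= ``mutual_coverage`` of BOTH sequences at >= ``identity``."""
    if not (0 < mutual_coverage <= 1 and 0 < identity <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    hits = {tid: False for tid, _ in lncrnas}
    if not published:
        return hits
    index = KmerIndex(k=12)
    lengths = {}
    for name, seq in published:
        index.add(name, seq)
        lengths[name] = len(seq)
    for tid, seq in lncrnas:
        blocks = _blocks_against(index, seq, identity)
        by_target: dict[str, list[dict]] = {}
        for b in blocks:
            by_target.setdefault(b["target"], []).append(b)
        for tname, tblocks in by_target.items():
            cov_q = covered_fraction(tblocks, len(seq), side="q")
            cov_t = covered_fraction(tblocks, lengths[tname], side="t")
            if cov_q >= mutual_coverage and cov_t >= mutual_coverage:
                hits[tid] = True
                break
    return hits


def read_support_conservation(
    lncrnas: list[tuple[str, str]],
    reads: list[tuple[str, str]],
    min_position_coverage: float = 0.80,
    min_identity: float = 0.90,
) -> dict[str, bool]:
    """Hit iff >= ``min_position_coverage`` of transcript positions are
    covered by >= 1 mapped read (gapless block at >= ``min_identity``)."""
    hits = {tid: False for tid, _ in lncrnas}
    if not reads:
        return hits
    index = KmerIndex(k=12)
    for name, seq in reads:
        index.add(name, seq)
    for tid, seq in lncrnas:
        blocks = _blocks_against(index, seq, min_identity)
        covered = union_length((b["qstart"], b["qend"]) for b in blocks)
        if covered / len(seq) >= min_position_coverage:
            hits[tid] = True
    return hits


def conservation_table(
    lncrnas: list[tuple[str, str]],
    references: dict[str, tuple[str, list[tuple[str, str]]]],
    min_coverage: float = 0.90,
    min_identity: float = 0.90,
    mutual_coverage: float = 0.75,
    read_coverage: float = 0.80,
) -> pd.DataFrame:
    """Per-lncRNA hit table over named references.

    ``references`` maps reference name -> (mode, records) with mode one of
    genome / transcripts / reads. ``exclusive`` is True iff every
    per-reference hit is False.
    """
    per_ref: dict[str, dict[str, bool]] = {}
    for name, (mode, records) in references.items():
        if mode == "genome":
            per_ref[name] = genome_conservation(lncrnas, records, min_coverage, min_identity)
        elif mode == "transcripts":
            per_ref[name] = transcript_set_conservation(
                lncrnas, records, mutual_coverage, min_identity
            )
        elif mode == "reads":
            per_ref[name] = read_support_conservation(
                lncrnas, records, read_coverage, min_identity
            )
        else:
            raise ValueError(f"unknown reference mode {mode!r}")
    rows = []
    for tid, _ in lncrnas:
        hit_row = {name: per_ref[name][tid] for name in references}
        shared = sum(hit_row.values())
        rows.append(
            {
                "transcript_id": tid,
                **hit_row,
                "shared_count": shared,
                "exclusive": shared == 0,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id", drop=False)


def tier_summary(table: pd.DataFrame, ref_names: list[str]) -> dict:
    """Venn partition over references: counts per membership subset,
    the exclusive count and the shared-with->=2 count."""
    venn: dict[tuple[str, ...], int] = {}
    for _, row in table.iterrows():
        subset = tuple(sorted(n for n in ref_names if row[n]))
        venn[subset] = venn.get(subset, 0) + 1
    return {
        "venn": venn,
        "exclusive": venn.get((), 0),
        "shared_two_or_more": sum(
            c for subset, c in venn.items() if len(subset) >= 2
        ),
        "total": int(len(table)),
    }
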