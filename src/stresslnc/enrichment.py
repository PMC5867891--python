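"""Hypergeometric GO over-representation of a gene set vs a background.

One-sided upper-tail hypergeometric test per term: with N background
genes of which K carry the term, and n target genes of which k carry it,
p = P(X >= k) for X ~ Hypergeom(N, K, n). No multiple-testing correction
by default (matching the plain p < 0.05 convention of the service this
replaces); Benjamini-Hochberg FDR is available behind a flag. When a
term parent map is supplied, gene annotations propagate to all ancestor
terms before testing.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .models import EnrichmentResult


def _propagate(terms: set[str], parents: dict[str, list[str]]) -> set[str]:
    out = set(terms)
    stack = list(terms)
    while stack:
        t = stack.pop()
        for p in parents.get(t, ()):
            if p not in out:
                out.add(p)
                stack.append(p)
    return out


def hypergeom_enrich(
    target: set[str],
    background: set[str],
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    parents: dict[str, list[str]] | None = None,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Test every annotated term for over-representation in ``target``.

    ``annotation`` has columns gene / term / namespace / name. The target
    set must be a subset of the background. Genes without annotation
    contribute to N and n but to no term's K or k.
    """
    if not target <= background:
        raise ValueError("target set is not a subset of the background")
    gene_terms: dict[str, set[str]] = {}
    term_info: dict[str, tuple[str, str]] = {}
    for _, row in annotation.iterrows():
        gene_terms.setdefault(row["gene"], set()).add(row["term"])
        term_info[row["term"]] = (row["name"], row["namespace"])
    if parents:
        gene_terms = {g: _propagate(ts, parents) for g, ts in gene_terms.items()}
        for t in {p for ps in parents.values() for p in ps}:
            term_info.setdefault(t, (t, "unknown"))
    N, n = len(background), len(target)
    results = []
    for term, (name, ns) in sorted(term_info.items()):
        K = sum(1 for g in background if term in gene_terms.get(g, ()))
        k = sum(1 for g in target if term in gene_terms.get(g, ()))
        if K == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                term_id=term,
                term_name=name,
                namespace=ns,
                k_in_set=k,
                K_in_background=K,
                n_set=n,
                N_background=N,
                p_value=min(1.0, p),
                enriched=False,
            )
        )
    if fdr and results:
        from statsmodels.stats.multitest import multipletests

        rej, padj, *_ = multipletests([r.p_value for r in results], alpha, "fdr_bh")
        for r, pa, rj in zip(results, padj, rej):
            r.p_adjusted = float(pa)
            r.enriched = bool(rj)
    else:
        for r in results:
            r.enriched = r.p_value < alpha
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "namespace": [r.namespace for r in results],
            "k": [r.k_in_set for r in results],
            "K": [r.K_in_background for r in results],
            "n": [r.n_set for r in results],
            "N": [r.N_background for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "enriched": [r.enriched for r in results],
        }
    )
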