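"""End-to-end orchestration over a study directory.

A study directory holds the standard-format inputs (as produced by
:func:`stresslnc.simulate.simulate_study` or assembled by hand):
transcripts.fa, contaminants.fa, proteins.fa, coding_ref.fa, mirnas.fa,
genes.gff3, aln.bed, counts.tsv, refs/*.fa, published_lncrnas.fa,
go_map.tsv, qpcr_ct.tsv, qpcr_dilution.tsv. ``run_study`` runs every
stage in order, writes per-stage TSVs under ``<study>/out/`` and returns
the stage tables; ``evaluate_against_truth`` scores the run against a
planted truth table when one is present.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from . import context as ctx
from . import conservation as cons
from . import expression as expr
from . import qpcr as qp
from . import transnat as tn
from .config import PipelineConfig
from .enrichment import enrichment_table, hypergeom_enrich
from .io import (
    read_bed12,
    read_counts,
    read_ct_table,
    read_fasta,
    read_gff3,
    read_go_map,
    write_fasta,
    write_gff3,
)
from .models import CONDITIONS, GeneModel, GenomeAnnotation
from .structure import structure_zscore

log = logging.getLogger("stresslnc")

HYBRID_MODES = {"hybrid_a": "genome", "hybrid_b": "genome", "hybrid_c": "reads"}


def run_study(
    study_dir: str | Path,
    config: PipelineConfig | None = None,
    n_structure: int = 60,
) -> dict:
    """Run the full pipeline on one study directory.

    ``n_structure`` caps how many lncRNAs get a folding z-score (the
    cubic folding program dominates runtime; a deterministic subsample is
    scored and the calibration claim is about rates, not individuals).
    """
    cfg = config or PipelineConfig()
    study = Path(study_dir)
    out = study / "out"
    out.mkdir(exist_ok=True)
    log.info("run_study start: dir=%s seed=%s config=%s", study, cfg.seed, cfg.digest())

    transcripts = read_fasta(study / "transcripts.fa")
    contaminants = read_fasta(study / "contaminants.fa")
    proteins = read_fasta(study / "proteins.fa")
    coding_ref = read_fasta(study / "coding_ref.fa")
    mirnas = read_fasta(study / "mirnas.fa")
    annotation = read_gff3(study / "genes.gff3")
    alignments = read_bed12(study / "aln.bed")
    counts = read_counts(study / "counts.tsv")

    # --- catalog ---------------------------------------------------------
    catalog_df = cat.run_cascade(
        transcripts, contaminants, proteins, mirnas, coding_ref, cfg
    )
    catalog_df.to_csv(out / "catalog.tsv", sep="\t", index=False)
    seq_of = dict(transcripts)
    lnc_ids = [
        t
        for t in catalog_df.index
        if catalog_df.at[t, "terminal_class"] == "lncRNA"
        and not catalog_df.at[t, "redundant"]
    ]
    lncrnas = [(t, seq_of[t]) for t in lnc_ids]
    write_fasta(out / "lncrna.fa", lncrnas)
    coding_ids = [
        t
        for t in catalog_df.index
        if catalog_df.at[t, "terminal_class"] in ("protein_match", "coding_predicted")
        and not catalog_df.at[t, "redundant"]
    ]
    log.info("catalog: %d transcripts, %d lncRNAs, %d coding", len(transcripts),
             len(lnc_ids), len(coding_ids))

    # --- genomic context -------------------------------------------------
    lnc_aln = [a for a in alignments if a.transcript_id in set(lnc_ids)]
    context_df = ctx.context_table(lnc_aln, annotation, lnc_ids)
    context_df.to_csv(out / "context.tsv", sep="\t", index=False)
    unique_aln = [
        a for a in lnc_aln if context_df.at[a.transcript_id, "mapping"] == "unique"
    ]
    exons = ctx.exon_count_histogram(unique_aln)
    # emitted lncRNA loci (uniquely mapped) and per-chromosome counts
    lnc_loci = GenomeAnnotation(
        chromosomes=annotation.chromosomes,
        genes=[
            GeneModel(a.transcript_id, a.chrom, "unknown", list(a.blocks), "lncRNA")
            for a in unique_aln
        ],
    )
    write_gff3(out / "lncrna_loci.gff3", lnc_loci)
    chrom_counts = pd.Series(
        [a.chrom for a in unique_aln], dtype=str
    ).value_counts().rename_axis("chrom").rename("n_lncrnas")
    chrom_counts.to_frame().to_csv(out / "chrom_counts.tsv", sep="\t")

    # --- expression ------------------------------------------------------
    lengths = pd.Series({t: len(s) for t, s in transcripts}, name="length")
    factors = expr.tmm_factors(counts, trim_m=cfg.tmm_trim_m, trim_a=cfg.tmm_trim_a)
    fpkm_df = expr.fpkm(counts, lengths)
    fpkm_df.to_csv(out / "fpkm.tsv", sep="\t", index_label="transcript_id")
    expressed = expr.expressed_set(fpkm_df, cfg.expressed_fpkm)
    de_df = expr.de_table(
        counts.loc[[t for t in counts.index if t in set(lnc_ids)]],
        factors,
        cfg.dispersion,
        cfg.fold_cutoff,
        cfg.p_cutoff,
        cfg.pseudo_count,
    )
    de_df.to_csv(out / "de.tsv", sep="\t", index=False)
    classes_df = expr.response_classes(de_df)
    classes_df.to_csv(out / "response_classes.tsv", sep="\t", index=False)
    expr.mean_normalized_counts(
        counts.loc[de_df.loc[de_df["is_de"], "transcript_id"].unique()], factors
    ).to_csv(out / "heatmap_matrix.tsv", sep="\t", index_label="transcript_id")

    # --- neighbor correlations ------------------------------------------
    # gene expression = FPKM of the coding transcript aligned to the gene
    gene_fpkm_rows = {}
    coding_aln = [a for a in alignments if a.transcript_id in set(coding_ids)]
    for a in coding_aln:
        for g in annotation.genes_on(a.chrom):
            if g.biotype == "coding" and g.start < a.end and a.start < g.end:
                gene_fpkm_rows.setdefault(g.gene_id, fpkm_df.loc[a.transcript_id])
    gene_fpkm = pd.DataFrame(gene_fpkm_rows).T
    if gene_fpkm.empty:
        gene_fpkm = pd.DataFrame(columns=list(CONDITIONS))
    neighbors_df = ctx.neighbor_correlations(
        unique_aln, annotation, fpkm_df, gene_fpkm, cfg.neighbor_window
    )
    neighbors_df.to_csv(out / "neighbors.tsv", sep="\t", index=False)

    # --- conservation ----------------------------------------------------
    references = {}
    for name, mode in HYBRID_MODES.items():
        path = study / "refs" / f"{name}.fa"
        if path.exists():
            references[name] = (mode, read_fasta(path))
    cons_df = cons.conservation_table(
        lncrnas,
        references,
        cfg.genome_coverage,
        cfg.genome_identity,
        cfg.mutual_coverage,
        cfg.read_support_coverage,
    )
    pub_path = study / "published_lncrnas.fa"
    if pub_path.exists():
        pub_hits = cons.transcript_set_conservation(
            lncrnas, read_fasta(pub_path), cfg.mutual_coverage, cfg.set_identity
        )
        cons_df["published_set"] = [pub_hits[t] for t in cons_df.index]
    cons_df.to_csv(out / "conservation.tsv", sep="\t", index=False)
    tier = cons.tier_summary(cons_df, list(references))
    pd.DataFrame(
        [
            {"subset": "+".join(s) or "exclusive", "count": c}
            for s, c in sorted(tier["venn"].items())
        ]
    ).to_csv(out / "venn_counts.tsv", sep="\t", index=False)

    # expression summary by conservation group
    group = pd.Series("coding", index=catalog_df.index)
    for t in lnc_ids:
        group[t] = "exclusive_lncRNA" if cons_df.at[t, "exclusive"] else "shared_lncRNA"
    keep = [t for t in catalog_df.index if t in set(lnc_ids) or t in set(coding_ids)]
    summary_df = expr.expression_summary(
        fpkm_df.loc[keep], group[keep], cfg.expressed_fpkm
    )
    summary_df.to_csv(out / "expression_summary.tsv", sep="\t", index=False)

    # --- trans-NATs ------------------------------------------------------
    coding_seqs = [(t, seq_of[t]) for t in coding_ids]
    pairs = tn.classify_pairs(
        tn.find_pairs(lncrnas, coding_seqs, min_align_len=50,
                      min_identity=cfg.nat_min_identity),
        cfg.nat_high_coverage,
        cfg.nat_min_run,
        cfg.nat_both_members,
    )
    pairs_df = pd.DataFrame(
        {
            "query_id": [p.query_id for p in pairs],
            "target_id": [p.target_id for p in pairs],
            "target_type": [p.target_type for p in pairs],
            "pair_class": [p.pair_class for p in pairs],
            "longest_run": [p.longest_run for p in pairs],
            "coverage_query": [p.coverage_query for p in pairs],
            "coverage_target": [p.coverage_target for p in pairs],
        }
    )
    pairs_df.to_csv(out / "pairs.tsv", sep="\t", index=False)
    categories = tn.coexpression_categories(pairs, expressed)
    coexp_df = tn.coexpression_table(categories)
    coexp_df.to_csv(out / "coexpression_table.tsv", sep="\t", index=False)
    de_lnc = set(de_df.loc[de_df["is_de"], "transcript_id"])
    ratio_df = tn.expression_ratio(pairs, fpkm_df, de_lnc, cfg.ratio_epsilon)
    ratio_df.to_csv(out / "ratio_matrix.tsv", sep="\t", index=False)
    top_df = tn.top_paired(pairs, k=5) if pairs else pd.DataFrame()
    top_df.to_csv(out / "top_paired.tsv", sep="\t", index=False)

    # --- structure -------------------------------------------------------
    rng = np.random.default_rng(cfg.seed + 101)
    sample = lnc_ids[:n_structure]
    zrows = []
    for t in sample:
        rec = structure_zscore(seq_of[t], cfg.n_shuffles, rng, transcript_id=t)
        zrows.append(
            {
                "transcript_id": t,
                "native_energy": rec.native_energy,
                "null_mean": rec.null_mean,
                "null_sd": rec.null_sd,
                "z": rec.z if rec.z is not None else float("nan"),
                "degenerate": rec.degenerate,
            }
        )
    struct_df = pd.DataFrame(zrows)
    struct_df.to_csv(out / "structure_z.tsv", sep="\t", index=False)

    # --- GO enrichment of trans-NAT target genes -------------------------
    go_df = read_go_map(study / "go_map.tsv")
    background = set(go_df["gene"]) | set(coding_ids)
    nat_targets = {p.target_id for p in pairs if p.target_type == "coding"}
    enr_df = pd.DataFrame()
    if nat_targets:
        results = hypergeom_enrich(
            nat_targets & background, background, go_df, cfg.enrich_alpha,
            fdr=cfg.enrich_fdr,
        )
        enr_df = enrichment_table(results)
        enr_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # --- qPCR ------------------------------------------------------------
    qpcr_folds = pd.DataFrame()
    qpcr_eff = pd.DataFrame()
    qpcr_cmp = {}
    ct_path = study / "qpcr_ct.tsv"
    if ct_path.exists():
        ct = read_ct_table(ct_path)
        qpcr_folds = qp.fold_table(ct, reference_target="REF_CUL")
        qpcr_folds.to_csv(out / "qpcr_folds.tsv", sep="\t", index=False)
        dil = pd.read_csv(study / "qpcr_dilution.tsv", sep="\t")
        qpcr_eff = pd.DataFrame(
            [
                {"target": t, **qp.efficiency(list(zip(sub["log10_input"], sub["ct"])))}
                for t, sub in dil.groupby("target")
            ]
        )
        qpcr_eff.to_csv(out / "qpcr_efficiency.tsv", sep="\t", index=False)
        qpcr_cmp = qp.compare_with_rnaseq(qpcr_folds, de_df)

    log.info("run_study done: %d lncRNAs, %d pairs", len(lnc_ids), len(pairs))
    return {
        "catalog": catalog_df,
        "context": context_df,
        "exons": exons,
        "neighbors": neighbors_df,
        "conservation": cons_df,
        "tier_summary": tier,
        "factors": factors,
        "fpkm": fpkm_df,
        "expressed": expressed,
        "de": de_df,
        "response_classes": classes_df,
        "expression_summary": summary_df,
        "pairs": pairs,
        "pairs_df": pairs_df,
        "coexpression": coexp_df,
        "categories": categories,
        "ratio": ratio_df,
        "top_paired": top_df,
        "structure": struct_df,
        "enrichment": enr_df,
        "qpcr_folds": qpcr_folds,
        "qpcr_efficiency": qpcr_eff,
        "qpcr_comparison": qpcr_cmp,
        "lnc_ids": lnc_ids,
        "coding_ids": coding_ids,
    }


def evaluate_against_truth(study_dir: str | Path, result: dict) -> dict:
    """Score a pipeline run against the planted truth of the simulator."""
    study = Path(study_dir)
    truth = pd.read_csv(study / "truth.tsv", sep="\t").set_index(
        "transcript_id", drop=False
    )
    nat_truth = pd.read_csv(study / "nat_truth.tsv", sep="\t")
    catalog_df = result["catalog"]
    metrics: dict[str, float] = {}

    planted_lnc = truth.index[truth["label"] == "lncRNA"]
    called_lnc = set(result["lnc_ids"])
    metrics["lncrna_recovery_pct"] = 100.0 * np.mean(
        [t in called_lnc for t in planted_lnc]
    )
    planted_cont = truth.index[truth["label"] == "contaminant"]
    metrics["contaminant_removal_pct"] = 100.0 * np.mean(
        [catalog_df.at[t, "terminal_class"] == "contaminant" for t in planted_cont]
    )
    planted_coding = truth.index[truth["label"] == "coding"]
    metrics["coding_detection_pct"] = 100.0 * np.mean(
        [
            catalog_df.at[t, "terminal_class"] in ("protein_match", "coding_predicted")
            for t in planted_coding
        ]
    )
    planted_red = truth.index[truth["label"] == "redundant"]
    if len(planted_red):
        metrics["redundancy_removal_pct"] = 100.0 * np.mean(
            [bool(catalog_df.at[t, "redundant"]) for t in planted_red]
        )

    # genomic classes among recovered, uniquely mapped lncRNAs
    ctx_df = result["context"]
    scored = [
        t
        for t in planted_lnc
        if t in called_lnc and truth.at[t, "n_placements"] == 1
        and ctx_df.at[t, "mapping"] == "unique"
    ]
    if scored:
        metrics["genomic_class_accuracy_pct"] = 100.0 * np.mean(
            [ctx_df.at[t, "genomic_class"] == truth.at[t, "genomic_class"] for t in scored]
        )
    # conservation / exclusivity
    cons_df = result["conservation"]
    in_cons = [t for t in planted_lnc if t in cons_df.index]
    if in_cons:
        metrics["exclusive_call_accuracy_pct"] = 100.0 * np.mean(
            [bool(cons_df.at[t, "exclusive"]) == bool(truth.at[t, "exclusive"])
             for t in in_cons]
        )
        metrics["exclusive_fraction_pct"] = 100.0 * float(
            cons_df["exclusive"].mean()
        )
    # DE response classes in the planted tissue
    classes = result["response_classes"].set_index(["transcript_id", "tissue"])
    de_planted = [
        t
        for t in planted_lnc
        if t in called_lnc and truth.at[t, "de_pattern"] not in ("none", "", None)
        and not pd.isna(truth.at[t, "de_pattern"])
    ]
    if de_planted:
        hits = []
        for t in de_planted:
            tis = truth.at[t, "de_tissue"]
            got = (
                classes.at[(t, tis), "response_class"]
                if (t, tis) in classes.index
                else "none"
            )
            hits.append(got == truth.at[t, "de_pattern"])
        metrics["de_class_recovery_pct"] = 100.0 * np.mean(hits)
    # trans-NAT pair recovery
    found = {
        tuple(sorted((p.query_id, p.target_id))) for p in result["pairs"]
    }
    planted_pairs = [
        tuple(sorted((r["lnc_id"], r["partner_id"])))
        for _, r in nat_truth.iterrows()
        if r["lnc_id"] in called_lnc
    ]
    if planted_pairs:
        metrics["nat_pair_recovery_pct"] = 100.0 * np.mean(
            [pp in found for pp in planted_pairs]
        )
    # miRNA precursor flags among recovered lncRNAs
    flagged_truth = [t for t in planted_lnc if t in called_lnc]
    if flagged_truth:
        metrics["mirna_flag_accuracy_pct"] = 100.0 * np.mean(
            [
                bool(catalog_df.at[t, "mirna_precursor"])
                == bool(truth.at[t, "mirna_precursor"])
                for t in flagged_truth
            ]
        )
    return metrics
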