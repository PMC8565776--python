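"""End-to-end orchestration on a synthetic dataset.

``run_pipeline`` generates a toy screen with known truth, then runs every
analysis stage in order — expression profiling, library design, count
filtering, enrichment, mixture hit calling, feature aggregation,
hit-feature statistics, and mechanism clustering — writing per-stage TSVs,
a JSON report of the quantities each stage computed, and the resolved
configuration into one results directory. Deterministic given config+seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, cluster, expression, features, hitstats, mixture
from . import screen as screen_mod
from . import simulate
from .config import PipelineConfig
from .io import write_table

log = logging.getLogger("lncscreen")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    chash = config.hash()
    seed = config.rng_seed
    ss = np.random.SeedSequence(seed).spawn(6)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    report: dict = {"seed": seed, "config_hash": chash}

    # --- synthetic inputs -------------------------------------------------
    transcripts, genome = simulate.gen_annotation(
        n_mrna=40, n_lnc=60, rng_seed=seeds[0], n_rna_mechanism=6
    )
    rna_mech = {
        t.gene_id for t in transcripts if t.gene_id.startswith("LNCRM")
    }
    expr, expr_samples, expr_truth = simulate.gen_expression(
        transcripts, rng_seed=seeds[1], rna_mechanism_ids=rna_mech
    )
    tracks = simulate.gen_feature_tracks(
        transcripts, rna_mechanism_ids=rna_mech, rng_seed=seeds[2]
    )
    annotation.write_gtf(transcripts, outdir / "annotation.gtf")

    # --- expression profiling --------------------------------------------
    spliced = expr[~expr.is_unspliced].drop(columns="is_unspliced")
    expressed_tx = expression.expressed_set(
        spliced, expr_samples, config.tpm_threshold, "transcript",
        config.expression_mode,
    )
    expressed_genes = expression.expressed_set(
        spliced, expr_samples, config.tpm_threshold, "gene",
        config.expression_mode,
    )
    gene_tbl = expression.gene_level(spliced)
    tau_genes = expression.tau_table(gene_tbl, expr_samples)
    biotype = gene_tbl.biotype
    tau_cmp = expression.specificity_compare(
        {
            "lncRNA": tau_genes[biotype == "lncRNA"],
            "mRNA": tau_genes[biotype == "protein_coding"],
        }
    )
    de = expression.simple_de_test(spliced, expr_samples, "endoderm", "hESC")
    report["expression"] = {
        "n_expressed_transcripts": len(expressed_tx),
        "n_expressed_genes": len(expressed_genes),
        "median_tau_lncRNA": float(tau_genes[biotype == "lncRNA"].median()),
        "median_tau_mRNA": float(tau_genes[biotype == "protein_coding"].median()),
    }
    write_table(
        pd.DataFrame({"gene_id": tau_genes.index, "tau": tau_genes.to_numpy()}),
        outdir / "tau.tsv", chash, seed,
    )
    write_table(tau_cmp, outdir / "tau_comparisons.tsv", chash, seed)
    write_table(de.reset_index(drop=True), outdir / "de_plumbing.tsv", chash, seed)

    # --- library design on the annotation --------------------------------
    lib_tbl, tss = simulate.build_library(
        transcripts, genome,
        expressed_transcripts=expressed_tx,
        guides_per_tss=config.guides_per_tss,
        rng_seed=seeds[3],
    )
    report["library"] = {
        "n_tss": len(tss),
        "n_guides": int(lib_tbl.shape[0]),
        "n_controls": int(lib_tbl.is_control.sum()),
    }
    write_table(lib_tbl.reset_index(drop=True), outdir / "library.tsv", chash, seed)

    # --- screen simulation + statistics ----------------------------------
    library, counts, samples, truth = simulate.simulate_screen_dataset(
        rng_seed=seeds[4]
    )
    truth.to_json(outdir / "sim_truth.json")
    counts.reset_index(drop=True).to_csv(outdir / "counts.tsv", sep="\t", index=False)

    targets = library.target_tss_id
    report_f = screen_mod.filter_cascade(
        counts, samples, targets,
        config.day0_cpm_min, config.undiff_cpm_min, config.min_guides_per_tss,
    )
    log.info("filter cascade: %s", report_f.counts)
    enr = screen_mod.estimate_enrichment(
        counts, samples, report_f.survivors, config.pseudocount
    )
    model, calls = mixture.call_screen(
        enr, targets, report_f.survivors,
        rng_seed=seeds[5], robust_null=config.robust_null,
        n_restarts=config.em_restarts, fdr_hit=config.fdr_hit,
        fdr_stringent=config.fdr_stringent_nonhit,
        min_stringent_guides=config.min_stringent_guides,
    )
    hits = set(calls.index[calls.is_hit])
    sens = (
        len(hits & truth.functional_tss_ids) / len(truth.functional_tss_ids)
        if truth.functional_tss_ids else float("nan")
    )
    fdp = (
        len(hits - truth.functional_tss_ids) / len(hits) if hits else 0.0
    )
    report["screen"] = {
        "filter_counts": report_f.counts,
        "n_hits": len(hits),
        "n_stringent_nonhits": int(calls.is_stringent_nonhit.sum()),
        "sensitivity_vs_truth": sens,
        "fdp_vs_truth": fdp,
        "null_sd": model.null_sd,
        "pi_guide": model.pi_guide,
    }
    write_table(enr.reset_index(drop=True), outdir / "guide_enrichment.tsv", chash, seed)
    write_table(calls.reset_index(drop=True), outdir / "tss_calls.tsv", chash, seed)

    # --- features + clustering -------------------------------------------
    panel = gene_tbl[[c for c in gene_tbl.columns if c not in ("gene_id", "biotype")]]
    feats = features.aggregate_features(
        transcripts, genome,
        cage_track=tracks["cage"],
        enhancer_track=tracks["enhancers"],
        conservation=features.ConservationTrack(tracks["conservation"]),
        expression_panel=panel,
        splicing=simulate.estimated_splicing(expr),
        extra_point_tracks={"endoderm_cancer_snp": tracks["endoderm_cancer_snps"]},
    )
    write_table(feats.reset_index(drop=True), outdir / "features.tsv", chash, seed)

    z, imputed = cluster.standardize(feats[features.CLUSTERING_FEATURES])
    assign = cluster.kmeans2(
        z, feats.biotype, rng_seed=seed, n_restarts=config.kmeans_restarts,
        k=config.k_clusters,
    )
    # hit genes in the clustering universe: use RNA-mechanism truth as the
    # synthetic analogue of the screen hit list for this toy annotation
    candidates, diag = cluster.label_mrna_like(
        assign, hit_genes=rna_mech, gold_standards=sorted(rna_mech)[:3]
    )
    report["clustering"] = {
        "n_clustered": int(assign.shape[0]),
        "n_mrna_like_lnc": int(
            ((assign.biotype == "lncRNA") & assign.mrna_like).sum()
        ),
        "n_candidate_rna_mechanism_hits": int(candidates.shape[0]),
        **diag,
    }
    write_table(assign.reset_index(drop=True), outdir / "clusters.tsv", chash, seed)

    # --- hit-feature statistics on the toy annotation ---------------------
    lnc_feats = feats[feats.biotype == "lncRNA"]
    mech = [g for g in lnc_feats.index if g in rna_mech]
    non = [g for g in lnc_feats.index if g not in rna_mech]
    if mech and non:
        cmp_tbl = hitstats.compare_hit_features(
            lnc_feats, mech, non, features=features.CLUSTERING_FEATURES,
            bh_fdr=config.bh_fdr,
        )
        write_table(cmp_tbl.reset_index(drop=True),
                    outdir / "feature_comparisons.tsv", chash, seed)
        report["feature_comparison"] = {
            "n_significant": int(cmp_tbl.significant.sum()),
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
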