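"""Reproduction of published summary counts from supplementary tables.

These loaders consume the screen's released supplementary tables (plain-text
TSVs) when a copy is available locally and re-derive the printed summary
counts from the raw columns: the three-stage filter cascade survivor totals,
the unique-guide count, the FDR<0.1 hit count, the stringent non-hit gene
count, the 0.1-tpm expressed transcript/gene counts, and the number of
mRNA-like lncRNA hits. The tables are multi-megabyte downloads and are not
bundled with the package; point ``data_dir`` at a directory holding them as

    S1_lncRNA_expression.tsv   transcript_id, gene_id, per-sample tpm
    S2_sgRNA_counts.tsv        sgRNA, target tss/transcript, per-sample counts
    S3_hit_calling.tsv         tss/transcript id, gene_id, biotype, FDR
    S7_clustering.tsv          gene_id, biotype, cluster / mrna_like
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .expression import expressed_set
from .io import read_table
from .screen import filter_cascade

S_FILES = {
    "S1": "S1_lncRNA_expression.tsv",
    "S2": "S2_sgRNA_counts.tsv",
    "S3": "S3_hit_calling.tsv",
    "S7": "S7_clustering.tsv",
}


def _find(df: pd.DataFrame, *cands: str) -> str:
    lower = {c.lower(): c for c in df.columns}
    for cand in cands:
        if cand in lower:
            return lower[cand]
    raise ValueError(f"none of {cands} found among columns {list(df.columns)}")


def load_s2_counts(path) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """S2 -> (counts, sample sheet, guide->TSS targets).

    Sample columns are recognized by name: day0/dayzero, undiff/double_neg,
    diff/double_pos, each suffixed with the replicate number.
    """
    df = read_table(path)
    gcol = _find(df, "sgrna", "guide_id", "sgrna_id", "guide")
    tcol = _find(df, "tss_id", "target", "target_tss_id", "transcript_id")
    df = df.set_index(gcol, drop=False)
    samples = []
    rename = {}
    for c in df.columns:
        cl = c.lower()
        for rep in ("1", "2"):
            if rep not in cl:
                continue
            if "day" in cl and ("0" in cl or "zero" in cl):
                pop = "day0"
            elif "undiff" in cl or "neg" in cl:
                pop = "undifferentiated"
            elif "diff" in cl or "pos" in cl:
                pop = "differentiated"
            else:
                continue
            name = f"{pop}_rep{rep}"
            rename[c] = name
            samples.append({"sample": name, "population": pop, "replicate": int(rep)})
            break
    counts = df[list(rename)].rename(columns=rename).astype(int)
    targets = df[tcol].astype(str)
    return counts, pd.DataFrame(samples), targets


def reproduce_printed_counts(data_dir) -> dict:
    """Re-derive every printed summary count from the supplementary tables.

    Raises FileNotFoundError when the tables are absent; never substitutes
    cached numbers.
    """
    data_dir = Path(data_dir)
    missing = [n for n in S_FILES.values() if not (data_dir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"supplementary tables not found under {data_dir}: {missing}"
        )
    out: dict = {}

    counts, samples, targets = load_s2_counts(data_dir / S_FILES["S2"])
    out["unique_sgrnas"] = int(counts.index.nunique())
    rep = filter_cascade(counts, samples, targets)
    out["after_day0_cpm5"] = rep.counts["after_stage1_day0_cpm"]
    out["after_undiff_cpm1"] = rep.counts["after_stage2_undiff_cpm"]
    out["after_min3_guides"] = rep.counts["after_stage3_min_guides"]
    out["tss_after_filters"] = rep.counts["tss_after_stage3"]
    out["scrambled_after_filters"] = rep.counts["scrambled_after_filters"]

    s3 = read_table(data_dir / S_FILES["S3"])
    fdr_col = _find(s3, "fdr", "global_fdr", "crisphiermix_fdr")
    gene_col = _find(s3, "gene_id", "gene", "gene_name")
    bio_col = _find(s3, "biotype", "gene_biotype", "type")
    out["hits_fdr_lt_0.1"] = int((s3[fdr_col] < 0.1).sum())

    # stringent non-hits need the per-TSS filtered-guide counts from S2
    tcol = _find(s3, "tss_id", "target", "transcript_id")
    surv = targets.loc[list(rep.survivors)]
    surv = surv[surv != "SCRAMBLED"]
    n_guides = surv.value_counts()
    s3 = s3.assign(_n_filtered=s3[tcol].astype(str).map(n_guides).fillna(0))
    is_lnc = s3[bio_col].astype(str).str.contains("lnc", case=False)
    stringent = s3[(s3[fdr_col] > 0.9) & (s3._n_filtered >= 9) & is_lnc]
    out["stringent_nonhit_genes"] = int(stringent[gene_col].nunique())

    s1 = read_table(data_dir / S_FILES["S1"])
    tx_col = _find(s1, "transcript_id", "target_id", "transcript")
    g1_col = _find(s1, "gene_id", "gene")
    sample_cols = [c for c in s1.columns if c not in (tx_col, g1_col)]
    numeric = s1[sample_cols].select_dtypes(include=[np.number])
    tbl = s1[[tx_col, g1_col]].rename(
        columns={tx_col: "transcript_id", g1_col: "gene_id"}
    ).assign(biotype="lncRNA").join(numeric).set_index("transcript_id", drop=False)
    sheet = pd.DataFrame(
        {"sample": numeric.columns,
         "lineage": [c.split("_")[0] for c in numeric.columns],
         "replicate": 1}
    )
    out["expressed_transcripts_0.1tpm"] = len(
        expressed_set(tbl, sheet, 0.1, "transcript", "any_sample")
    )
    out["expressed_genes_0.1tpm"] = len(
        expressed_set(tbl, sheet, 0.1, "gene", "any_sample")
    )

    s7 = read_table(data_dir / S_FILES["S7"])
    g7 = _find(s7, "gene_id", "gene", "gene_name")
    try:
        mcol = _find(s7, "mrna_like")
        mrna_like_genes = set(s7.loc[s7[mcol].astype(bool), g7])
    except ValueError:
        ccol = _find(s7, "cluster", "kmeans_cluster")
        b7 = _find(s7, "biotype", "gene_biotype")
        frac = s7.groupby(ccol)[b7].apply(
            lambda s: s.astype(str).str.contains("protein").mean()
        )
        mrna_cluster = frac.idxmax()
        mrna_like_genes = set(s7.loc[s7[ccol] == mrna_cluster, g7])
    hit_genes = set(s3.loc[(s3[fdr_col] < 0.1) & is_lnc, gene_col])
    out["mrna_like_lnc_hits"] = len(hit_genes & mrna_like_genes)
    return out


PRINTED_COUNTS = {
    "unique_sgrnas": 111_801,
    "after_day0_cpm5": 76_091,
    "after_undiff_cpm1": 57_384,
    "after_min3_guides": 55_804,
    "tss_after_filters": 9_771,
    "scrambled_after_filters": 2_690,
    "hits_fdr_lt_0.1": 73,
    "stringent_nonhit_genes": 158,
    "expressed_transcripts_0.1tpm": 12_611,
    "expressed_genes_0.1tpm": 8_190,
    "mrna_like_lnc_hits": 6,
}
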