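"""Expression thresholding, tau tissue specificity, and plumbing DE.

Expression tables are wide DataFrames indexed by transcript_id with
``gene_id`` and ``biotype`` metadata columns and one tpm column per sample;
a companion sample sheet maps sample -> (lineage, replicate).

tau for a gene expressed at x_1..x_n across n lineages:

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1)

0 for ubiquitous expression, 1 for single-lineage expression; undefined
(NaN) when the gene is silent everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

META_COLS = ("transcript_id", "gene_id", "biotype", "is_unspliced")

DEFAULT_TPM_THRESHOLD = 0.1


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def lineage_means(table: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Average tpm per lineage across replicates (columns = lineages)."""
    cols = {}
    for lineage, sub in samples.groupby("lineage", sort=False):
        cols[lineage] = table[list(sub["sample"])].mean(axis=1)
    return pd.DataFrame(cols)


def gene_level(table: pd.DataFrame) -> pd.DataFrame:
    """Gene-level tpm = sum of the gene's transcript tpm, per sample."""
    cols = sample_columns(table)
    g = table.groupby("gene_id")[cols].sum()
    bt = table.groupby("gene_id")["biotype"].first()
    out = g.copy()
    out.insert(0, "gene_id", out.index)
    out.insert(1, "biotype", bt)
    return out


def expressed_set(
    table: pd.DataFrame,
    samples: pd.DataFrame,
    threshold_tpm: float = DEFAULT_TPM_THRESHOLD,
    level: str = "transcript",
    mode: str = "lineage_mean",
) -> set[str]:
    """IDs expressed at >= threshold in at least one lineage.

    ``mode="lineage_mean"`` (default) averages replicates per lineage before
    thresholding; ``mode="any_sample"`` thresholds raw samples.
    """
    if level == "gene":
        table = gene_level(table)
    elif level != "transcript":
        raise ValueError(f"level must be transcript/gene, got {level!r}")
    if mode == "lineage_mean":
        values = lineage_means(table, samples)
    elif mode == "any_sample":
        values = table[sample_columns(table)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = (values >= threshold_tpm).any(axis=1)
    return set(values.index[keep])


@dataclass
class TauResult:
    id: str
    tau: float
    n_lineages: int
    lineage_means: np.ndarray
    normalized: np.ndarray


def tau(x, id: str = "") -> TauResult:
    """Tissue-specificity statistic of one expression vector across lineages."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a vector over >= 2 lineages")
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    m = x.max()
    if m == 0:
        return TauResult(id, float("nan"), x.size, x, np.full_like(x, np.nan))
    xhat = x / m
    value = float((1 - xhat).sum() / (x.size - 1))
    return TauResult(id, value, x.size, x, xhat)


def tau_table(table: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
    """tau per row, on replicate-averaged lineage means."""
    means = lineage_means(table, samples)
    arr = means.to_numpy(dtype=float)
    maxima = arr.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (1 - arr / maxima[:, None]).sum(axis=1) / (arr.shape[1] - 1)
    vals[maxima == 0] = np.nan
    return pd.Series(vals, index=means.index, name="tau")


def specificity_compare(tau_by_group: dict[str, pd.Series]) -> pd.DataFrame:
    """Summaries plus pairwise two-sided rank-sum tests between groups.

    Groups with fewer than 2 finite values are skipped. Returns one row per
    ordered pair with medians and the Mann-Whitney two-sided p-value.
    """
    clean = {
        k: v.dropna() for k, v in tau_by_group.items() if v.dropna().size >= 2
    }
    rows = []
    names = list(clean)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            u, p = stats.mannwhitneyu(clean[a], clean[b], alternative="two-sided")
            rows.append(
                {"group_a": a, "group_b": b,
                 "median_a": float(clean[a].median()),
                 "median_b": float(clean[b].median()),
                 "n_a": clean[a].size, "n_b": clean[b].size,
                 "u_statistic": float(u), "p_value": float(p)}
            )
    return pd.DataFrame(rows)


def simple_de_test(
    table: pd.DataFrame,
    samples: pd.DataFrame,
    lineage_a: str,
    lineage_b: str,
    pseudo_tpm: float = 0.01,
) -> pd.DataFrame:
    """t-test on log2(tpm + pseudo) with variance pooled across transcripts.

    Plumbing for synthetic pipelines only — not the likelihood-ratio DE
    model used on real screens; every output row is flagged accordingly.
    The residual variance is pooled over all transcripts (the synthetic
    generator is homoskedastic on the log scale, where per-transcript
    variance estimates at n = 2 would have ~1 df and no power), giving a
    t statistic with the summed residual df; BH across transcripts.
    Zero-variance transcripts get p = 1 with a flag.
    """
    cols_a = list(samples.loc[samples.lineage == lineage_a, "sample"])
    cols_b = list(samples.loc[samples.lineage == lineage_b, "sample"])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("simple_de_test needs >= 2 replicates per lineage")
    a = np.log2(table[cols_a].to_numpy(dtype=float) + pseudo_tpm)
    b = np.log2(table[cols_b].to_numpy(dtype=float) + pseudo_tpm)
    na, nb = a.shape[1], b.shape[1]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = len(ss) * (na + nb - 2)
    pooled_var = ss.sum() / df if df > 0 else 0.0
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    if pooled_var > 0:
        tstat = log2fc / np.sqrt(pooled_var * (1 / na + 1 / nb))
        p = 2 * stats.t.sf(np.abs(tstat), df)
    else:
        p = np.ones_like(log2fc)
    p = np.where(zero_var, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "transcript_id": table.index,
            "gene_id": table["gene_id"].to_numpy() if "gene_id" in table else table.index,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "zero_variance": zero_var,
            "method": "pooled_t_plumbing_not_screen_de",
        }
    ).set_index("transcript_id", drop=False)
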