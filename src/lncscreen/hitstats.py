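"""Downstream statistics over hit vs. stringent-non-hit loci.

Validation scoring of individually tested guides, per-feature Mann-Whitney
comparisons with Benjamini-Hochberg correction, and the Fisher exact test of
association between hit status and differential expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PCT_FLOOR = 0.1  # pseudo-percentage for empty FACS gates
DEFAULT_BH_FDR = 0.10


def validation_score(
    pct_undiff: float,
    pct_diff: float,
    pct_undiff_scrambled: float,
    pct_diff_scrambled: float,
) -> float:
    """Enrichment of undifferentiated cells relative to a matched scrambled
    control measured in the same differentiation batch:

        log2[ (u / d) / (u_scr / d_scr) ]

    Percentages of zero are floored at 0.1% to keep the ratio defined (the
    caller is warned). The exact published formula lives only in a figure
    graphic; this default definition is deliberately isolated here so it can
    be swapped via ``PipelineConfig.validation_score_fn``.
    """
    vals = []
    for v in (pct_undiff, pct_diff, pct_undiff_scrambled, pct_diff_scrambled):
        if not (0 <= v <= 100):
            raise ValueError(f"percentage out of range: {v}")
        if v == 0:
            warnings.warn("zero percentage floored at 0.1%")
            v = PCT_FLOOR
        vals.append(v)
    u, d, us, ds = vals
    return float(np.log2((u / d) / (us / ds)))


def compare_hit_features(
    feature_table: pd.DataFrame,
    hit_genes,
    nonhit_genes,
    features: list[str] | None = None,
    bh_fdr: float = DEFAULT_BH_FDR,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney per feature, hits vs stringent non-hits.

    Returns one row per feature: U statistic, two-sided p, BH-adjusted FDR,
    group medians, and a significance flag at ``bh_fdr``. Features with no
    finite values in either group are skipped with a warning.
    """
    hit_genes = [g for g in hit_genes if g in feature_table.index]
    nonhit_genes = [g for g in nonhit_genes if g in feature_table.index]
    if not hit_genes or not nonhit_genes:
        raise ValueError("both groups must be non-empty")
    if features is None:
        features = [
            c for c in feature_table.columns
            if c not in ("gene_id", "biotype") and
            pd.api.types.is_numeric_dtype(feature_table[c])
        ]
    rows = []
    for feat in features:
        a = feature_table.loc[hit_genes, feat].dropna()
        b = feature_table.loc[nonhit_genes, feat].dropna()
        if a.empty or b.empty:
            warnings.warn(f"feature {feat!r} has an all-missing group; skipped")
            continue
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {"feature": feat, "u_statistic": float(u), "p_value": float(p),
             "median_hit": float(a.median()), "median_nonhit": float(b.median()),
             "n_hit": int(a.size), "n_nonhit": int(b.size)}
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr_bh"] = multipletests(out.p_value, method="fdr_bh")[1]
        out["significant"] = out.fdr_bh < bh_fdr
    return out.set_index("feature", drop=False)


def de_hit_association(
    hit_ids, nonhit_ids, de_flags: pd.Series, odds_ratio: str = "sample"
) -> dict:
    """2x2 association between hit status and differential expression.

    ``de_flags``: id -> bool (differentially expressed). Returns the table
    [[hit&DE, hit&notDE], [nonhit&DE, nonhit&notDE]], the odds ratio
    (``"sample"`` = ad/bc, default; ``"cmle"`` = conditional MLE), and the
    two-sided Fisher exact p-value. A zero margin yields a NaN odds ratio.
    """
    hit_ids = [i for i in hit_ids if i in de_flags.index]
    nonhit_ids = [i for i in nonhit_ids if i in de_flags.index]
    a = int(de_flags.loc[hit_ids].sum())
    b = len(hit_ids) - a
    c = int(de_flags.loc[nonhit_ids].sum())
    d = len(nonhit_ids) - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if odds_ratio == "sample":
        orv = (a * d) / (b * c) if b * c > 0 else float("nan")
        if b * c == 0 and a * d == 0:
            orv = float("nan")
    elif odds_ratio == "cmle":
        res = stats.contingency.odds_ratio(table, kind="conditional")
        orv = float(res.statistic)
    else:
        raise ValueError(f"unknown odds_ratio kind {odds_ratio!r}")
    return {"table": table, "odds_ratio": float(orv), "p_value": float(p)}
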