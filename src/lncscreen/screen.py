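"""Screen count processing: cpm, the three-stage filter cascade, and
batch-paired enrichment estimation.

Count tables are integer DataFrames (rows = guide_id, columns = samples)
with a sample sheet mapping sample -> (population, replicate), population
in {day0, differentiated, undifferentiated}. Positive log2 fold-change
means enrichment in the undifferentiated pool, i.e. drop-out of
differentiation upon knockdown.

The enrichment estimator is a replicate-paired normalized log-ratio:
median-of-ratios size factors across the sorted samples, then per guide and
replicate log2((undiff + c)/(diff + c)) with pseudo-count c, averaged over
replicates with a between-replicate standard error. Replicate pairing
absorbs batch effects the way a batch term in a count GLM would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POPULATIONS = ("day0", "differentiated", "undifferentiated")
DAY0_CPM_MIN = 5.0
UNDIFF_CPM_MIN = 1.0
MIN_GUIDES_PER_TSS = 3
DEFAULT_PSEUDOCOUNT = 0.5


def check_samples(samples: pd.DataFrame) -> None:
    bad = set(samples.population) - set(POPULATIONS)
    if bad:
        raise ValueError(f"unknown populations {sorted(bad)}")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample (raw library size, no size factors)."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"empty sample column(s): {empty}")
    return counts / totals * 1e6


@dataclass
class FilterReport:
    """Survivors of each filter stage, plus the per-stage counts the screen
    reports (guides after each stage; TSSs after stage 3)."""

    stage1: set[str]
    stage2: set[str]
    stage3: set[str]
    n_tss_after: int
    n_scrambled_after: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def survivors(self) -> set[str]:
        return self.stage3


def filter_cascade(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    guide_targets: pd.Series,
    day0_cpm_min: float = DAY0_CPM_MIN,
    undiff_cpm_min: float = UNDIFF_CPM_MIN,
    min_guides_per_tss: int = MIN_GUIDES_PER_TSS,
) -> FilterReport:
    """Three consecutive filters that remove noisy guides.

    1. keep guides with cpm >= ``day0_cpm_min`` in *every* day-0 replicate;
    2. of those, keep guides with cpm >= ``undiff_cpm_min`` in every
       undifferentiated replicate;
    3. drop guides whose target TSS has fewer than ``min_guides_per_tss``
       survivors of stages 1-2. Scrambled guides (target NaN/"SCRAMBLED")
       have no TSS and are exempt from stage 3.

    ``guide_targets``: guide_id -> target tss id (scrambled = NaN or
    "SCRAMBLED"); multi-target guides may carry ";"-joined ids.
    """
    check_samples(samples)
    day0_cols = list(samples.loc[samples.population == "day0", "sample"])
    undiff_cols = list(samples.loc[samples.population == "undifferentiated", "sample"])
    if not day0_cols or not undiff_cols:
        raise ValueError("filter cascade needs day0 and undifferentiated samples")

    rates = cpm(counts)
    s1_mask = (rates[day0_cols] >= day0_cpm_min).all(axis=1)
    stage1 = set(counts.index[s1_mask])
    s2_mask = s1_mask & (rates[undiff_cols] >= undiff_cpm_min).all(axis=1)
    stage2 = set(counts.index[s2_mask])

    targets = guide_targets.reindex(counts.index)
    is_scrambled = targets.isna() | (targets == "SCRAMBLED")

    # count stage-1-2 survivors per TSS (a multi-target guide counts for each)
    tss_counts: dict[str, int] = {}
    for gid in counts.index[s2_mask & ~is_scrambled]:
        for tss in str(targets[gid]).split(";"):
            tss_counts[tss] = tss_counts.get(tss, 0) + 1

    keep_tss = {t for t, n in tss_counts.items() if n >= min_guides_per_tss}
    stage3 = set()
    for gid in stage2:
        if is_scrambled[gid]:
            stage3.add(gid)
        elif any(t in keep_tss for t in str(targets[gid]).split(";")):
            stage3.add(gid)

    n_scrambled_after = sum(1 for g in stage2 if is_scrambled[g])
    report = FilterReport(
        stage1=stage1,
        stage2=stage2,
        stage3=stage3,
        n_tss_after=len(keep_tss),
        n_scrambled_after=n_scrambled_after,
    )
    report.counts = {
        "input_guides": int(counts.shape[0]),
        "after_stage1_day0_cpm": len(stage1),
        "after_stage2_undiff_cpm": len(stage2),
        "after_stage3_min_guides": len(stage3),
        "tss_after_stage3": report.n_tss_after,
        "scrambled_after_filters": n_scrambled_after,
    }
    return report


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference) over samples."""
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_ref = np.log(arr).mean(axis=1)
    usable = np.isfinite(log_ref)
    if usable.sum() == 0:
        raise ValueError("no guide has non-zero counts in every sample")
    with np.errstate(divide="ignore"):
        log_ratios = np.log(arr[usable]) - log_ref[usable, None]
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_enrichment(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    filtered_guides: set[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-guide log2 fold-change undifferentiated vs differentiated.

    Size factors are fit by median-of-ratios across the sorted samples only
    (day-0 samples describe initial representation, not sorting). Per
    replicate r: lfc_r = log2((u_r + c)/(d_r + c)) on normalized counts;
    the estimate is the mean over replicates and the standard error the
    between-replicate sd / sqrt(n_reps).
    """
    check_samples(samples)
    sorted_samples = samples[samples.population.isin(["differentiated", "undifferentiated"])]
    reps = sorted(sorted_samples.replicate.unique())
    pairs = []
    for r in reps:
        sub = sorted_samples[sorted_samples.replicate == r]
        u = sub.loc[sub.population == "undifferentiated", "sample"]
        d = sub.loc[sub.population == "differentiated", "sample"]
        if len(u) != 1 or len(d) != 1:
            raise ValueError(f"replicate {r}: need one undiff and one diff sample")
        pairs.append((u.iloc[0], d.iloc[0]))
    if not pairs:
        raise ValueError("no complete replicate pair")

    if filtered_guides is not None:
        counts = counts.loc[counts.index.isin(filtered_guides)]
    cols = [s for pair in pairs for s in pair]
    sf = size_factors_median_of_ratios(counts[cols])
    norm = counts[cols] / sf

    per_rep = np.column_stack(
        [
            np.log2((norm[u].to_numpy() + pseudocount) / (norm[d].to_numpy() + pseudocount))
            for u, d in pairs
        ]
    )
    lfc = per_rep.mean(axis=1)
    se = (
        per_rep.std(axis=1, ddof=1) / np.sqrt(per_rep.shape[1])
        if per_rep.shape[1] > 1
        else np.full(len(lfc), np.nan)
    )
    out = pd.DataFrame(
        {"guide_id": counts.index, "log2fc": lfc, "standard_error": se},
        index=counts.index,
    )
    for i, (u, d) in enumerate(pairs, start=1):
        out[f"undiff_norm_rep{i}"] = norm[u].to_numpy()
        out[f"diff_norm_rep{i}"] = norm[d].to_numpy()
    return out
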