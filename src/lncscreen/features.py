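"""Per-gene genomic feature aggregation.

Eleven features enter the downstream mechanism clustering:

========================  ====================================================
max_transcript_length     max spliced (exon-sum) length across transcripts, nt
max_exon_count            max exon count across transcripts
mean_gc                   mean transcript GC fraction across transcripts
locus_length              max TSS-to-3'-end genomic span (introns included), nt
n_cage_tss_100bp          CAGE TSS clusters within 100 bp of the TSS, same strand
n_enhancers_1mb           enhancers within 1 Mb of the TSS (either side)
dist_closest_enhancer     bp from TSS to the closest enhancer (0 if inside)
tss_conservation_200bp    mean conservation over TSS +/- 100 bp, max over transcripts
exon_conservation         mean conservation over exonic bases, max over transcripts
max_expression            max tpm across an expression panel
splicing_efficiency       spliced / (spliced + unspliced) abundance
==========================  ==================================================

Distance-to-track features that do not enter clustering (nearest SNP,
nearest histone peak, ...) are computed by the same primitives and kept in
separate columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

CLUSTERING_FEATURES = [
    "max_transcript_length",
    "max_exon_count",
    "mean_gc",
    "locus_length",
    "n_cage_tss_100bp",
    "n_enhancers_1mb",
    "dist_closest_enhancer",
    "tss_conservation_200bp",
    "exon_conservation",
    "max_expression",
    "splicing_efficiency",
]

CAGE_TSS_WINDOW_BP = 100
ENHANCER_WINDOW_BP = 1_000_000
CONSERVATION_TSS_WINDOW_BP = 200


def splicing_efficiency(spliced_tpm, unspliced_tpm: float) -> float:
    """Fraction of a gene's abundance carried by spliced transcripts.

    ``spliced_tpm`` may be a scalar or a per-transcript vector; returns
    ``sum(spliced) / (sum(spliced) + unspliced)``, or NaN when the gene is
    entirely unexpressed.
    """
    spliced = float(np.sum(spliced_tpm))
    unspliced = float(unspliced_tpm)
    if spliced < 0 or unspliced < 0:
        raise ValueError("abundances must be non-negative")
    total = spliced + unspliced
    if total == 0:
        return float("nan")
    return spliced / total


def gc_fraction(seq: str) -> float:
    """GC fraction of a nucleotide sequence (case-insensitive)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def nearest_feature_distance(
    query_start: int,
    query_end: int,
    track: pd.DataFrame,
    *,
    chrom: str,
    strand: str | None = None,
) -> float:
    """Minimum edge-to-edge distance from a query interval to a track.

    ``track`` has 0-based half-open columns chrom/start/end (and strand when
    strand matching is requested). Returns 0 when the query overlaps an
    interval and NaN for an empty (or chromosome-empty) track.
    """
    if query_start >= query_end:
        raise ValueError("query interval must be non-empty (half-open)")
    if track is None or len(track) == 0:
        return float("nan")
    sub = track[track.chrom == chrom]
    if strand is not None:
        sub = sub[sub.strand == strand]
    if sub.empty:
        return float("nan")
    starts = sub.start.to_numpy()
    ends = sub["end"].to_numpy()
    # gap between half-open intervals; <=0 means overlap
    gap = np.maximum(starts - query_end, query_start - ends) + 1
    return float(max(int(gap.min()), 0))


def count_within_window(
    position: int,
    track: pd.DataFrame,
    window_bp: int,
    *,
    chrom: str,
    strand: str | None = None,
) -> int:
    """Number of track intervals with any base within ``window_bp`` of a point.

    ``position`` is 0-based; point tracks are stored as 1-bp intervals.
    """
    if track is None or len(track) == 0:
        return 0
    sub = track[track.chrom == chrom]
    if strand is not None:
        sub = sub[sub.strand == strand]
    if sub.empty:
        return 0
    starts = sub.start.to_numpy()
    ends = sub["end"].to_numpy()
    gap = np.maximum(starts - (position + 1), position - ends) + 1
    return int((np.maximum(gap, 0) <= window_bp).sum())


class ConservationTrack:
    """Per-base conservation summaries from a bedGraph-like table.

    The table carries 0-based half-open intervals with a score column;
    uncovered bases score 0.
    """

    def __init__(self, table: pd.DataFrame):
        self.by_chrom = {
            c: sub.sort_values("start").reset_index(drop=True)
            for c, sub in table.groupby("chrom")
        }

    def mean_score(self, chrom: str, start: int, end: int) -> float:
        if start >= end:
            raise ValueError("empty window")
        sub = self.by_chrom.get(chrom)
        if sub is None:
            return 0.0
        s = np.maximum(sub.start.to_numpy(), start)
        e = np.minimum(sub["end"].to_numpy(), end)
        covered = np.maximum(e - s, 0)
        return float((covered * sub.score.to_numpy()).sum() / (end - start))

    def mean_score_intervals(self, chrom: str, intervals) -> float:
        total_bp = sum(e - s for s, e in intervals)
        if total_bp == 0:
            raise ValueError("no bases in intervals")
        acc = sum(self.mean_score(chrom, s, e) * (e - s) for s, e in intervals)
        return acc / total_bp


def aggregate_features(
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    *,
    cage_track: pd.DataFrame | None = None,
    enhancer_track: pd.DataFrame | None = None,
    conservation: ConservationTrack | None = None,
    expression_panel: pd.DataFrame | None = None,
    splicing: pd.Series | None = None,
    extra_point_tracks: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Build the per-gene feature table.

    Per-transcript quantities are reduced by max (lengths, exon count,
    conservation) or mean (GC); ``expression_panel`` is a gene x sample tpm
    table reduced by max; ``splicing`` is a per-gene splicing-efficiency
    series. Missing tracks yield NaN features, recorded per gene in the
    companion ``<name>_missing`` boolean columns only where imputation will
    later apply. ``extra_point_tracks`` produce ``dist_closest_<name>``
    columns kept apart from the 11 clustering features.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    rows = []
    for gene_id, ts in sorted(by_gene.items()):
        if not ts:
            raise ValueError(f"{gene_id}: gene with zero transcripts")
        chrom, strand = ts[0].chrom, ts[0].strand
        tss0 = (
            min(t.five_prime for t in ts) if strand == "+" else max(t.five_prime for t in ts)
        )
        row: dict[str, object] = {
            "gene_id": gene_id,
            "biotype": ts[0].biotype,
            "max_transcript_length": max(t.spliced_length for t in ts),
            "max_exon_count": max(t.n_exons for t in ts),
            "locus_length": max(t.locus_length for t in ts),
        }
        if genome:
            seq = genome[chrom]
            gcs = [
                gc_fraction("".join(seq[s:e] for s, e in t.exons)) for t in ts
            ]
            row["mean_gc"] = float(np.mean(gcs))
        else:
            row["mean_gc"] = float("nan")

        row["n_cage_tss_100bp"] = (
            count_within_window(tss0, cage_track, CAGE_TSS_WINDOW_BP,
                                chrom=chrom, strand=strand)
            if cage_track is not None
            else float("nan")
        )
        if enhancer_track is not None:
            row["n_enhancers_1mb"] = count_within_window(
                tss0, enhancer_track, ENHANCER_WINDOW_BP, chrom=chrom
            )
            row["dist_closest_enhancer"] = nearest_feature_distance(
                tss0, tss0 + 1, enhancer_track, chrom=chrom
            )
        else:
            row["n_enhancers_1mb"] = float("nan")
            row["dist_closest_enhancer"] = float("nan")

        if conservation is not None:
            half = CONSERVATION_TSS_WINDOW_BP // 2
            row["tss_conservation_200bp"] = max(
                conservation.mean_score(
                    chrom, max(t.five_prime - half, 0), t.five_prime + half
                )
                for t in ts
            )
            row["exon_conservation"] = max(
                conservation.mean_score_intervals(chrom, t.exons) for t in ts
            )
        else:
            row["tss_conservation_200bp"] = float("nan")
            row["exon_conservation"] = float("nan")

        row["max_expression"] = (
            float(expression_panel.loc[gene_id].max())
            if expression_panel is not None and gene_id in expression_panel.index
            else float("nan")
        )
        row["splicing_efficiency"] = (
            float(splicing.get(gene_id, float("nan"))) if splicing is not None
            else float("nan")
        )

        for name, track in (extra_point_tracks or {}).items():
            gene_start = min(t.start for t in ts)
            gene_end = max(t.end for t in ts)
            row[f"dist_closest_{name}"] = nearest_feature_distance(
                gene_start, gene_end, track, chrom=chrom
            )
        rows.append(row)

    df = pd.DataFrame(rows).set_index("gene_id", drop=False)
    return df
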