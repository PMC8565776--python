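"""Transcript models, lncRNA genomic-context categories, and TSS assignment.

Internally all interval arithmetic is 0-based half-open; GTF input/output is
1-based inclusive (pyranges performs the conversion on read), and point
coordinates such as TSS positions are reported 1-based to match GTF.

lncRNA categories follow the proximity rules used for CRISPRi screen design:
a locus is *promoter-overlapping* if its transcription start lies within
1 kb of a protein-coding gene start, *transcript-overlapping* if any of its
transcripts physically overlaps a protein-coding transcript, *gene-nearby*
if a protein-coding gene start/end lies within 1 kb of its gene start/end,
and *intergenic* otherwise; the rules are tested in that order and the
first that fires wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROMOTER_WINDOW_BP = 1000
NEARBY_WINDOW_BP = 1000
CAGE_WINDOW_BP = 400

CATEGORIES = (
    "promoter_overlapping",
    "transcript_overlapping",
    "gene_nearby",
    "intergenic",
)

TSS_SOURCES = ("fantom_cat_explicit", "cage_proximal", "annotated_5prime")


@dataclass
class TranscriptModel:
    """One transcript: exon structure plus biotype flags.

    ``exons`` are 0-based half-open ``(start, end)`` pairs, sorted and
    pairwise non-overlapping; ``coding_orf_flag`` marks transcripts carrying
    a conserved ORF (precomputed upstream) that disqualifies them as bona
    fide non-coding RNAs.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "lncRNA"
    coding_orf_flag: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in exons:
            if not 0 <= s < e:
                raise ValueError(f"{self.transcript_id}: bad exon ({s},{e})")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def five_prime(self) -> int:
        """0-based position of the first transcribed base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def locus_length(self) -> int:
        """Genomic distance from the TSS to the 3' end, introns included."""
        return self.end - self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class TSSRecord:
    """A screening TSS: 1-based point coordinate plus its provenance rule."""

    tss_id: str
    chrom: str
    strand: str
    position: int  # 1-based
    source: str
    transcript_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.source not in TSS_SOURCES:
            raise ValueError(f"unknown TSS source {self.source!r}")
        if self.position < 1:
            raise ValueError("TSS position is 1-based and must be >= 1")


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def read_gtf(path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file (exon features required)."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    exons = df[df.Feature == "exon"]
    if exons.empty:
        raise ValueError(f"{path}: GTF contains no exon features")
    biotype_col = next(
        (c for c in ("gene_biotype", "gene_type", "biotype") if c in exons.columns),
        None,
    )
    orf_col = "coding_orf_flag" if "coding_orf_flag" in exons.columns else None
    out: list[TranscriptModel] = []
    for (tid), sub in exons.groupby("transcript_id", sort=True, observed=True):
        first = sub.iloc[0]
        out.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene_id=str(first.gene_id),
                chrom=str(first.Chromosome),
                strand=str(first.Strand),
                exons=list(zip(sub.Start.astype(int), sub.End.astype(int))),
                biotype=str(first[biotype_col]) if biotype_col else "lncRNA",
                coding_orf_flag=(
                    str(first[orf_col]).lower() in ("true", "1") if orf_col else False
                ),
            )
        )
    return out


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    """Write transcript models as GTF (1-based inclusive, deterministic order)."""
    lines = []
    for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_biotype "{t.biotype}"; coding_orf_flag "{t.coding_orf_flag}";'
        )
        lines.append(
            "\t".join(
                [t.chrom, "lncscreen", "transcript", str(t.start + 1), str(t.end),
                 ".", t.strand, ".", attrs]
            )
        )
        for s, e in t.exons:
            lines.append(
                "\t".join(
                    [t.chrom, "lncscreen", "exon", str(s + 1), str(e),
                     ".", t.strand, ".", attrs]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def gene_table(transcripts: list[TranscriptModel]) -> pd.DataFrame:
    """Per-gene spans: strand-agnostic genomic min/max plus strand-aware TSS.

    ``tss`` is the 5' end of the 5'-most transcript (0-based); ``start``/``end``
    are the genomic span of all transcripts.
    """
    rows = {}
    for t in transcripts:
        r = rows.setdefault(
            t.gene_id,
            {"gene_id": t.gene_id, "chrom": t.chrom, "strand": t.strand,
             "start": t.start, "end": t.end, "biotype": t.biotype,
             "coding_orf_flag": t.coding_orf_flag},
        )
        r["start"] = min(r["start"], t.start)
        r["end"] = max(r["end"], t.end)
        r["coding_orf_flag"] = r["coding_orf_flag"] or t.coding_orf_flag
    df = pd.DataFrame(rows.values())
    df["tss"] = np.where(df.strand == "+", df.start, df["end"] - 1)
    return df.set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# lncRNA categorization
# ---------------------------------------------------------------------------

def categorize_lncrna(
    lnc_transcripts: list[TranscriptModel],
    pc_transcripts: list[TranscriptModel],
    *,
    promoter_rule_partner: str = "tss",
) -> str:
    """Assign one genomic-context category to one lncRNA gene.

    Parameters
    ----------
    lnc_transcripts
        All transcripts of the lncRNA gene (same gene_id).
    pc_transcripts
        All protein-coding transcripts on the assembly.
    promoter_rule_partner
        Which protein-coding coordinate the 1-kb promoter rule compares the
        lncRNA TSS against: ``"tss"`` (strand-aware transcription start,
        default) or ``"gene_start"`` (strand-agnostic genomic gene start).
    """
    if not lnc_transcripts:
        raise ValueError("lncRNA gene has no transcripts")
    if any(t.biotype == "protein_coding" for t in lnc_transcripts):
        raise ValueError("categorize_lncrna called on a protein-coding gene")
    if not pc_transcripts:
        return "intergenic"
    if promoter_rule_partner not in ("tss", "gene_start"):
        raise ValueError(f"bad promoter_rule_partner {promoter_rule_partner!r}")

    chrom = lnc_transcripts[0].chrom
    lnc_tss = (
        min(t.five_prime for t in lnc_transcripts)
        if lnc_transcripts[0].strand == "+"
        else max(t.five_prime for t in lnc_transcripts)
    )
    lnc_start = min(t.start for t in lnc_transcripts)
    lnc_end = max(t.end for t in lnc_transcripts)

    pc_genes = gene_table([t for t in pc_transcripts if t.chrom == chrom])
    if pc_genes.empty:
        return "intergenic"

    # Rule 1: lncRNA gene start within 1 kb of a protein-coding gene start.
    partner = pc_genes.tss if promoter_rule_partner == "tss" else pc_genes.start
    if (np.abs(partner.to_numpy() - lnc_tss) <= PROMOTER_WINDOW_BP).any():
        return "promoter_overlapping"

    # Rule 2: any lncRNA transcript overlaps a protein-coding transcript.
    for lt in lnc_transcripts:
        for pt in pc_transcripts:
            if pt.chrom == chrom and lt.start < pt.end and pt.start < lt.end:
                return "transcript_overlapping"

    # Rule 3: a protein-coding gene start/end within 1 kb of the lncRNA
    # gene start/end (strand-agnostic genomic coordinates).
    pc_edges = np.concatenate(
        [pc_genes.start.to_numpy(), pc_genes["end"].to_numpy() - 1]
    )
    for edge in (lnc_start, lnc_end - 1):
        if (np.abs(pc_edges - edge) <= NEARBY_WINDOW_BP).any():
            return "gene_nearby"

    return "intergenic"


def categorize_all(
    transcripts: list[TranscriptModel], *, promoter_rule_partner: str = "tss"
) -> pd.Series:
    """Categorize every non-coding-ORF lncRNA gene in an annotation."""
    pc = [t for t in transcripts if t.biotype == "protein_coding"]
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        if t.biotype == "lncRNA" and not t.coding_orf_flag:
            by_gene.setdefault(t.gene_id, []).append(t)
    cats = {
        g: categorize_lncrna(ts, pc, promoter_rule_partner=promoter_rule_partner)
        for g, ts in sorted(by_gene.items())
    }
    return pd.Series(cats, name="category", dtype="object")


# ---------------------------------------------------------------------------
# TSS assignment
# ---------------------------------------------------------------------------

def assign_tss(
    t: TranscriptModel,
    explicit_tss: int | None = None,
    cage_clusters: pd.DataFrame | None = None,
    *,
    window_bp: int = CAGE_WINDOW_BP,
) -> TSSRecord:
    """Assign a screening TSS to a transcript by a three-rule fallback.

    1. an explicitly curated TSS (1-based) wins outright;
    2. else the closest same-strand CAGE cluster within ``window_bp`` of the
       annotated 5' end (``cage_clusters``: columns chrom/strand/position,
       1-based); equidistant peaks break toward the 5'-most position on the
       transcript's strand;
    3. else the annotated 5' end itself.
    """
    five_prime_1b = t.five_prime + 1
    if explicit_tss is not None:
        pos, source = int(explicit_tss), "fantom_cat_explicit"
    else:
        pos, source = five_prime_1b, "annotated_5prime"
        if cage_clusters is not None and len(cage_clusters):
            sub = cage_clusters[
                (cage_clusters.chrom == t.chrom) & (cage_clusters.strand == t.strand)
            ]
            if len(sub):
                positions = np.sort(sub.position.to_numpy())
                dist = np.abs(positions - five_prime_1b)
                best = dist.min()
                if best <= window_bp:
                    tied = positions[dist == best]
                    pos = int(tied.min() if t.strand == "+" else tied.max())
                    source = "cage_proximal"
    return TSSRecord(
        tss_id=f"{t.chrom}:{pos}:{t.strand}",
        chrom=t.chrom,
        strand=t.strand,
        position=pos,
        source=source,
        transcript_ids={t.transcript_id},
    )


def assign_all_tss(
    transcripts: list[TranscriptModel],
    explicit: dict[str, int] | None = None,
    cage_clusters: pd.DataFrame | None = None,
) -> list[TSSRecord]:
    explicit = explicit or {}
    return [
        assign_tss(t, explicit.get(t.transcript_id), cage_clusters)
        for t in transcripts
    ]
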