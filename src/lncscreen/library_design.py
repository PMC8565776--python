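"""CRISPRi guide library assembly.

TSS consolidation, top-k guide selection from externally ranked candidates,
scrambled negative-control construction (random letter permutations of
sampled targeting guides, rejecting any scramble with an exact genome
match), and sequence-level deduplication with target-set union.

Guide scoring/ranking itself is consumed from input (an external designer
produces per-TSS candidate ranks); it is never recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import TSSRecord

SCRAMBLED = "SCRAMBLED"
GUIDE_LENGTH = 20
DEFAULT_GUIDES_PER_TSS = 10
DEFAULT_N_SCRAMBLE_SEEDS = 500
DEFAULT_N_PER_SEED = 10

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class GuideRecord:
    guide_id: str
    sequence: str
    target_tss_ids: set[str] = field(default_factory=set)
    candidate_rank: int = 1
    is_control: bool = False

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.guide_id}: non-ACGT sequence")
        if self.is_control and self.target_tss_ids:
            raise ValueError("scrambled controls carry no target TSS")


def consolidate_tss(tss_records: list[TSSRecord]) -> list[TSSRecord]:
    """Merge TSS records with identical (chrom, strand, position).

    Transcript sets are unioned; coordinates are never fuzz-merged here
    (proximal-TSS collapsing happens upstream during TSS assignment).
    """
    merged: dict[tuple, TSSRecord] = {}
    for r in tss_records:
        key = (r.chrom, r.strand, r.position)
        if key in merged:
            merged[key].transcript_ids |= r.transcript_ids
        else:
            merged[key] = TSSRecord(
                tss_id=r.tss_id, chrom=r.chrom, strand=r.strand,
                position=r.position, source=r.source,
                transcript_ids=set(r.transcript_ids),
            )
    return [merged[k] for k in sorted(merged, key=lambda k: (k[0], k[2], k[1]))]


def select_guides(
    candidates: pd.DataFrame, k: int = DEFAULT_GUIDES_PER_TSS
) -> tuple[list[GuideRecord], list[str]]:
    """Top-k ranked candidates per TSS.

    ``candidates`` columns: tss_id, sequence, rank (1 = best). Returns the
    selected guides plus a skip report of TSS ids with zero candidates
    (callers pass the full TSS universe via rows with NaN sequence).
    """
    guides: list[GuideRecord] = []
    skipped: list[str] = []
    for tss_id, sub in candidates.groupby("tss_id", sort=True):
        sub = sub.dropna(subset=["sequence"])
        if sub.empty:
            skipped.append(str(tss_id))
            continue
        sub = sub.sort_values("rank", kind="stable").head(k)
        for _, row in sub.iterrows():
            guides.append(
                GuideRecord(
                    guide_id=f"{tss_id}|rank{int(row['rank'])}",
                    sequence=str(row["sequence"]),
                    target_tss_ids={str(tss_id)},
                    candidate_rank=int(row["rank"]),
                )
            )
    return guides, skipped


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def genome_contains(sequence: str, genome: dict[str, str] | None) -> bool:
    """Exact substring match on either strand of any chromosome."""
    if not genome:
        return False
    rc = _revcomp(sequence)
    return any(sequence in chrom_seq or rc in chrom_seq for chrom_seq in genome.values())


def make_scrambled_controls(
    library: list[GuideRecord],
    n_seed: int = DEFAULT_N_SCRAMBLE_SEEDS,
    n_per_seed: int = DEFAULT_N_PER_SEED,
    genome: dict[str, str] | None = None,
    rng_seed: int = 0,
    max_tries: int = 1000,
) -> list[GuideRecord]:
    """Scrambled negative controls: ``n_seed`` sampled targeting guides, each
    letter-permuted ``n_per_seed`` times.

    Scrambles with an exact genome match (either strand) are rejected and
    re-drawn, so controls can never collide with targeting sequences drawn
    from the genome; each scramble preserves its seed's length and
    nucleotide composition. Seeds with < 2 distinct letters cannot be
    scrambled non-identically and are replaced (with a warning).
    """
    import warnings

    targeting = [g for g in library if not g.is_control]
    if n_seed > len(targeting):
        raise ValueError(f"n_seed={n_seed} exceeds library size {len(targeting)}")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(targeting))
    pool = iter(order)

    controls: list[GuideRecord] = []
    n_done = 0
    while n_done < n_seed:
        try:
            seed_guide = targeting[next(pool)]
        except StopIteration:
            raise RuntimeError("exhausted library while replacing degenerate seeds")
        if len(set(seed_guide.sequence)) < 2:
            warnings.warn(
                f"seed {seed_guide.guide_id} has < 2 distinct letters; re-drawing"
            )
            continue
        letters = np.array(list(seed_guide.sequence))
        for j in range(n_per_seed):
            for _ in range(max_tries):
                scramble = "".join(rng.permutation(letters))
                if scramble != seed_guide.sequence and not genome_contains(
                    scramble, genome
                ):
                    break
            else:
                raise RuntimeError(
                    f"could not scramble {seed_guide.guide_id} in {max_tries} tries"
                )
            controls.append(
                GuideRecord(
                    guide_id=f"scrambled|{seed_guide.guide_id}|{j}",
                    sequence=scramble,
                    target_tss_ids=set(),
                    candidate_rank=1,
                    is_control=True,
                )
            )
        n_done += 1
    return controls


def dedup_library(guides: list[GuideRecord]) -> list[GuideRecord]:
    """Collapse identical sequences; multi-target guides union their TSS sets."""
    merged: dict[str, GuideRecord] = {}
    for g in guides:
        if g.sequence in merged:
            kept = merged[g.sequence]
            kept.target_tss_ids |= g.target_tss_ids
            kept.candidate_rank = min(kept.candidate_rank, g.candidate_rank)
            kept.is_control = kept.is_control and g.is_control
        else:
            merged[g.sequence] = replace(
                g, target_tss_ids=set(g.target_tss_ids)
            )
    return list(merged.values())


def library_table(guides: list[GuideRecord]) -> pd.DataFrame:
    """Flat TSV-ready view of a guide library."""
    return pd.DataFrame(
        {
            "guide_id": [g.guide_id for g in guides],
            "sequence": [g.sequence for g in guides],
            "target_tss_id": [
                ";".join(sorted(g.target_tss_ids)) if g.target_tss_ids else SCRAMBLED
                for g in guides
            ],
            "rank": [g.candidate_rank for g in guides],
            "is_control": [g.is_control for g in guides],
        }
    ).set_index("guide_id", drop=False)


def write_fasta(guides: list[GuideRecord], path) -> None:
    with open(path, "w") as fh:
        for g in guides:
            fh.write(f">{g.guide_id}\n{g.sequence}\n")
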