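"""Synthetic screen generator with serialized ground truth.

Everything the analysis consumes can be generated here with known truth:
a toy genome + annotation realizing a requested lncRNA category mix, a
3-lineage x 2-replicate expression table with controlled tissue specificity
and splicing efficiency, guide candidate lists drawn from the genome, and
FACS-sorted count tables.

The count model mirrors the structure a sorted CRISPRi drop-out screen
assumes: every cell carries one guide; knocking down a functional TSS
multiplies a cell's odds of failing differentiation by 2**effect; only a
subset of a functional TSS's guides are effective (two-point efficiency
mixture by default, a Beta option exists); undifferentiated pools are
sorted conservatively (smaller samples); replicates differ by
multiplicative batch offsets; reads are multinomial draws from the pool
composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, TSSRecord, assign_all_tss
from .library_design import (
    GuideRecord,
    consolidate_tss,
    dedup_library,
    library_table,
    make_scrambled_controls,
    select_guides,
)

LINEAGES = ("hESC", "endoderm", "mesoderm")

# study-condition defaults for the screen-statistics simulations
N_TSS_DEFAULT = 1000
GUIDES_PER_TSS_DEFAULT = 10
N_FUNCTIONAL_DEFAULT = 50
N_SCRAMBLED_DEFAULT = 1000
PI_DEFAULT = 0.5
DEPTH_DEFAULT = 500            # expected day-0 reads per guide
SORTING_STRINGENCY_DEFAULT = 0.5  # undiff pool sequenced at this fraction of depth
SORT_NOISE_SDLOG_DEFAULT = 0.35   # per-(guide,pool,replicate) lognormal sorting noise
BASE_UNDIFF_RATE_DEFAULT = 0.2    # baseline P(cell fails differentiation)
BATCH_OFFSETS_DEFAULT = (1.0, 0.7)
ABUNDANCE_SDLOG_DEFAULT = 0.5


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _make_transcript(tid, gid, chrom, strand, start, end, n_exons, biotype):
    """Evenly laid-out exon chain spanning [start, end)."""
    if n_exons == 1:
        exons = [(start, end)]
    else:
        span = end - start
        exon_len = max(span // (2 * n_exons - 1), 50)
        exons = []
        pos = start
        for i in range(n_exons):
            e = min(pos + exon_len, end) if i < n_exons - 1 else end
            exons.append((pos, e))
            pos = e + exon_len
        exons = [(s, e) for s, e in exons if s < e]
    return TranscriptModel(tid, gid, chrom, strand, exons, biotype=biotype)


def gen_annotation(
    n_mrna: int = 30,
    n_lnc: int = 40,
    category_mix: dict[str, int] | None = None,
    rng_seed: int = 0,
    n_rna_mechanism: int = 0,
    matched_structure: bool = False,
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Toy genome + annotation realizing ``category_mix`` exactly.

    ``category_mix`` maps category -> lncRNA count (defaults to an even
    split of ``n_lnc``); running the categorizer on the output recovers the
    mix exactly, which the tests assert as a round trip. Protein-coding
    genes are spaced 50 kb apart so the 1-kb proximity rules are controlled
    entirely by construction.

    ``n_rna_mechanism`` designates that many intergenic lncRNAs (gene ids
    ``LNCRM*``) as RNA-mechanism analogues with mRNA-like gene structure
    (long, multi-exonic). ``matched_structure=True`` gives *every* lncRNA
    mRNA-like structural statistics, so structural features carry no
    biotype signal and any downstream separation must come from expression,
    splicing, and conservation.
    """
    rng = np.random.default_rng(rng_seed)
    if category_mix is None:
        q, r = divmod(n_lnc, 4)
        category_mix = {
            "intergenic": q + (r > 0),
            "promoter_overlapping": q + (r > 1),
            "transcript_overlapping": q + (r > 2),
            "gene_nearby": q,
        }
    if sum(category_mix.values()) != n_lnc:
        raise ValueError("category_mix must sum to n_lnc")
    n_hosted = sum(v for k, v in category_mix.items() if k != "intergenic")
    if n_mrna == 0 and n_hosted > 0:
        raise ValueError("non-intergenic lncRNAs need protein-coding hosts")
    if n_rna_mechanism > category_mix.get("intergenic", 0):
        raise ValueError("n_rna_mechanism exceeds the intergenic count")

    chrom = "chrS1"
    spacing = 50_000
    transcripts: list[TranscriptModel] = []
    pc_slots = []
    slot = 0
    for i in range(n_mrna):
        start = 10_000 + slot * spacing
        gene_len = int(rng.integers(4_000, 8_000))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"MRNA{i:04d}"
        transcripts.append(
            _make_transcript(f"{gid}.t1", gid, chrom, strand, start,
                             start + gene_len, int(rng.integers(3, 6)),
                             "protein_coding")
        )
        pc_slots.append((start, start + gene_len, strand))
        slot += 1

    host = 0
    li = 0

    def next_host():
        nonlocal host
        s = pc_slots[host % len(pc_slots)]
        host += 1
        return s

    def lnc_shape(mrna_like: bool):
        if mrna_like or matched_structure:
            return int(rng.integers(4_000, 8_000)), int(rng.integers(3, 6))
        return int(rng.integers(800, 2_500)), 2

    def add_lnc(start, length, strand, n_exons, gid=None):
        nonlocal li
        if gid is None:
            gid = f"LNC{li:04d}"
        transcripts.append(
            _make_transcript(f"{gid}.t1", gid, chrom, strand, start,
                             start + length, n_exons, "lncRNA")
        )
        li += 1
        return gid

    placed: dict[str, list[str]] = {c: [] for c in category_mix}
    for _ in range(category_mix.get("promoter_overlapping", 0)):
        ps, pe, pstrand = next_host()
        length, nex = lnc_shape(False)
        # divergent: opposite strand, TSS 300 bp upstream of the pc TSS
        if pstrand == "+":
            tss = ps - 300
            placed["promoter_overlapping"].append(
                add_lnc(tss - length + 1, length, "-", nex)
            )
        else:
            tss = pe - 1 + 300
            placed["promoter_overlapping"].append(add_lnc(tss, length, "+", nex))
    for _ in range(category_mix.get("transcript_overlapping", 0)):
        ps, pe, _ = next_host()
        length, nex = lnc_shape(False)
        # sense-strand start inside the gene body, >1 kb from every pc TSS
        placed["transcript_overlapping"].append(
            add_lnc(ps + 1_500, length, "+", nex)
        )
    for _ in range(category_mix.get("gene_nearby", 0)):
        ps, pe, pstrand = next_host()
        length, nex = lnc_shape(False)
        # just past the pc 3' end, no overlap, >1 kb from every pc TSS
        if pstrand == "+":
            placed["gene_nearby"].append(add_lnc(pe + 300, length, "+", nex))
        else:
            placed["gene_nearby"].append(
                add_lnc(ps - 300 - length, length, "-", nex)
            )
    n_intergenic = category_mix.get("intergenic", 0)
    for j in range(n_intergenic):
        start = 10_000 + slot * spacing
        is_rm = j >= n_intergenic - n_rna_mechanism
        length, nex = lnc_shape(is_rm)
        gid = f"LNCRM{li:04d}" if is_rm else None
        placed["intergenic"].append(
            add_lnc(start, length, "+" if rng.random() < 0.5 else "-", nex,
                    gid=gid)
        )
        slot += 1

    genome_len = max(t.end for t in transcripts) + 10_000
    genome = {
        chrom: "".join(rng.choice(list("ACGT"), size=genome_len))
    }
    return transcripts, genome


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression(
    transcripts: list[TranscriptModel],
    rng_seed: int = 0,
    noise_cv: float = 0.1,
    frac_specific_lnc: float = 0.7,
    frac_specific_mrna: float = 0.3,
    frac_silent: float = 0.1,
    rna_mechanism_ids: set[str] | None = None,
    n_replicates: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """3-lineage expression table with controlled specificity and splicing.

    Lineage-specific genes put ~98% of their expression in one lineage
    (tau of the generating means ~0.99); ubiquitous genes are near-flat
    (tau ~< 0.2). Replicate noise is lognormal at ``noise_cv``. Per gene, an
    ``<gene>_unspliced`` pseudo-transcript row realizes a splicing-
    efficiency ground truth (high for mRNAs and designated RNA-mechanism
    lncRNAs, low otherwise). Returns (table, sample sheet, truth).
    """
    rng = np.random.default_rng(rng_seed)
    rna_mech = rna_mechanism_ids or set()
    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, []).append(t)

    samples = pd.DataFrame(
        [
            {"sample": f"{lin}_rep{r}", "lineage": lin, "replicate": r}
            for lin in LINEAGES
            for r in range(1, n_replicates + 1)
        ]
    )
    sdlog = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    truth_gene = {}
    for gid, ts in sorted(genes.items()):
        is_mrna = ts[0].biotype == "protein_coding"
        mrna_like = is_mrna or gid in rna_mech
        silent = rng.random() < frac_silent and not mrna_like
        specific = rng.random() < (
            frac_specific_mrna if is_mrna else frac_specific_lnc
        )
        base = float(rng.lognormal(3.0 if mrna_like else 1.0, 1.0))
        if silent:
            means = np.zeros(3)
        elif specific:
            means = np.full(3, 0.02 * base)
            means[rng.integers(0, 3)] = base
        else:
            means = base * rng.lognormal(0.0, 0.15, size=3)
        spl = (
            float(rng.uniform(0.75, 0.98)) if mrna_like else float(rng.uniform(0.05, 0.55))
        )
        truth_gene[gid] = {
            "lineage_means": means.tolist(),
            "specific": bool(specific),
            "silent": bool(silent),
            "splicing_efficiency": spl,
            "mrna_like_profile": bool(mrna_like),
        }
        shares = rng.dirichlet(np.ones(len(ts))) if len(ts) > 1 else np.ones(1)
        for t, share in zip(ts, shares):
            spliced_means = means * share * spl
            vals = {
                s["sample"]: float(
                    spliced_means[LINEAGES.index(s["lineage"])]
                    * rng.lognormal(-sdlog**2 / 2, sdlog)
                )
                for _, s in samples.iterrows()
            }
            rows.append({"transcript_id": t.transcript_id, "gene_id": gid,
                         "biotype": t.biotype, "is_unspliced": False, **vals})
        unspliced_means = means * (1 - spl)
        vals = {
            s["sample"]: float(
                unspliced_means[LINEAGES.index(s["lineage"])]
                * rng.lognormal(-sdlog**2 / 2, sdlog)
            )
            for _, s in samples.iterrows()
        }
        rows.append({"transcript_id": f"{gid}_unspliced", "gene_id": gid,
                     "biotype": ts[0].biotype, "is_unspliced": True, **vals})

    table = pd.DataFrame(rows).set_index("transcript_id", drop=False)
    truth = {"genes": truth_gene, "noise_cv": noise_cv, "rng_seed": rng_seed}
    return table, samples, truth


def estimated_splicing(table: pd.DataFrame) -> pd.Series:
    """Per-gene splicing efficiency from a generated expression table."""
    from .features import splicing_efficiency

    sample_cols = [
        c for c in table.columns
        if c not in ("transcript_id", "gene_id", "biotype", "is_unspliced")
    ]
    out = {}
    for gid, sub in table.groupby("gene_id"):
        spliced = sub.loc[~sub.is_unspliced, sample_cols].to_numpy().sum()
        unspliced = sub.loc[sub.is_unspliced, sample_cols].to_numpy().sum()
        out[gid] = splicing_efficiency(spliced, unspliced)
    return pd.Series(out, name="splicing_efficiency")


# ---------------------------------------------------------------------------
# feature tracks
# ---------------------------------------------------------------------------

def gen_feature_tracks(
    transcripts: list[TranscriptModel],
    rna_mechanism_ids: set[str] | None = None,
    rng_seed: int = 0,
    n_enhancers: int = 60,
    n_snps: int = 40,
) -> dict:
    """Auxiliary BED-like tracks: CAGE TSS clusters, enhancers, a
    conservation summary, and trait-associated SNPs.

    Exon conservation is drawn high for mRNAs and RNA-mechanism lncRNAs and
    low for other lncRNAs, so that clustering separation is carried by the
    features known to drive it (splicing efficiency, maximum expression,
    exon conservation).
    """
    rng = np.random.default_rng(rng_seed)
    rna_mech = rna_mechanism_ids or set()
    chrom = transcripts[0].chrom
    span_end = max(t.end for t in transcripts) + 5_000

    cage, cons = [], []
    for t in transcripts:
        p = t.five_prime
        cage.append({"chrom": t.chrom, "start": p, "end": p + 1, "strand": t.strand})
        if rng.random() < 0.4:  # secondary nearby cluster
            q = p + int(rng.integers(-80, 81))
            cage.append({"chrom": t.chrom, "start": max(q, 0), "end": max(q, 0) + 1,
                         "strand": t.strand})
        mrna_like = t.biotype == "protein_coding" or t.gene_id in rna_mech
        exon_score = rng.uniform(0.6, 0.95) if mrna_like else rng.uniform(0.02, 0.3)
        tss_score = rng.uniform(0.3, 0.7)
        half = 100
        cons.append({"chrom": t.chrom, "start": max(p - half, 0), "end": p + half,
                     "score": float(tss_score)})
        for s, e in t.exons:
            cons.append({"chrom": t.chrom, "start": s, "end": e,
                         "score": float(exon_score)})

    enh_pos = rng.integers(0, span_end, size=n_enhancers)
    enhancers = pd.DataFrame(
        {"chrom": chrom, "start": enh_pos, "end": enh_pos + 200}
    ).sort_values("start").reset_index(drop=True)
    snp_pos = rng.integers(0, span_end, size=n_snps)
    snps = pd.DataFrame(
        {"chrom": chrom, "start": snp_pos, "end": snp_pos + 1}
    ).sort_values("start").reset_index(drop=True)
    return {
        "cage": pd.DataFrame(cage),
        "enhancers": enhancers,
        "conservation": pd.DataFrame(cons),
        "endoderm_cancer_snps": snps,
    }


# ---------------------------------------------------------------------------
# guide library
# ---------------------------------------------------------------------------

def gen_guide_candidates(
    tss_records: list[TSSRecord],
    genome: dict[str, str],
    n_candidates: int = 12,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Ranked guide candidates per TSS, drawn as genome 20-mers near the TSS
    (stands in for an external designer's pre-ranked output)."""
    rng = np.random.default_rng(rng_seed)
    rows = []
    for rec in tss_records:
        seq = genome[rec.chrom]
        center = rec.position - 1
        offsets = rng.choice(np.arange(-150, 131), size=n_candidates, replace=False)
        for rank, off in enumerate(offsets, start=1):
            s = int(np.clip(center + off, 0, len(seq) - 20))
            rows.append({"tss_id": rec.tss_id, "sequence": seq[s:s + 20],
                         "rank": rank})
    return pd.DataFrame(rows)


def build_library(
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    expressed_transcripts: set[str] | None = None,
    guides_per_tss: int = 10,
    n_scramble_seeds: int = 50,
    n_per_seed: int = 10,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, list[TSSRecord]]:
    """Design a screen-ready library for a toy annotation: assign + merge
    TSSs, select top-ranked guides, add scrambled controls, dedup."""
    ts = transcripts
    if expressed_transcripts is not None:
        ts = [t for t in ts if t.transcript_id in expressed_transcripts]
    tss = consolidate_tss(assign_all_tss(ts))
    candidates = gen_guide_candidates(tss, genome, rng_seed=rng_seed)
    guides, _ = select_guides(candidates, k=guides_per_tss)
    controls = make_scrambled_controls(
        guides, n_seed=min(n_scramble_seeds, len(guides)),
        n_per_seed=n_per_seed, genome=genome, rng_seed=rng_seed,
    )
    lib = dedup_library(guides + controls)
    return library_table(lib), tss


def make_screen_library_frame(
    n_tss: int = N_TSS_DEFAULT,
    guides_per_tss: int = GUIDES_PER_TSS_DEFAULT,
    n_scrambled: int = N_SCRAMBLED_DEFAULT,
) -> pd.DataFrame:
    """Abstract guide->TSS frame for screen-statistics simulations (no
    sequences needed)."""
    rows = [
        {"guide_id": f"TSS{t:05d}_g{g}", "target_tss_id": f"TSS{t:05d}",
         "is_control": False}
        for t in range(n_tss)
        for g in range(guides_per_tss)
    ]
    rows += [
        {"guide_id": f"scr_{i:05d}", "target_tss_id": "SCRAMBLED",
         "is_control": True}
        for i in range(n_scrambled)
    ]
    return pd.DataFrame(rows).set_index("guide_id", drop=False)


# ---------------------------------------------------------------------------
# truth + counts
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth serialized next to every generated count table."""

    functional_tss_ids: set[str]
    guide_efficiency: dict[str, float]
    tss_effect: dict[str, float]
    batch_offsets: dict[int, float]
    rng_seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["functional_tss_ids"] = sorted(self.functional_tss_ids)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["functional_tss_ids"] = set(d["functional_tss_ids"])
        d["batch_offsets"] = {int(k): v for k, v in d["batch_offsets"].items()}
        return cls(**d)


def make_sim_truth(
    library: pd.DataFrame,
    n_functional: int = N_FUNCTIONAL_DEFAULT,
    effect_log2: float = 1.0,
    pi: float = PI_DEFAULT,
    efficiency_model: str = "two_point",
    beta_params: tuple[float, float] = (2.0, 2.0),
    batch_offsets: tuple[float, ...] = BATCH_OFFSETS_DEFAULT,
    rng_seed: int = 0,
    functional_tss_ids: set[str] | None = None,
) -> SimTruth:
    """Plant functional TSSs and per-guide efficiencies.

    ``two_point``: a guide of a functional TSS is fully effective with
    probability ``pi`` and inert otherwise (the subset-of-guides-that-work
    assumption); ``beta``: efficiencies drawn Beta(*beta_params*).
    Non-functional TSSs have effect 0 by construction. An explicit
    ``functional_tss_ids`` set overrides the random draw.
    """
    rng = np.random.default_rng(rng_seed)
    targeted = sorted(
        {t for t in library.target_tss_id if t != "SCRAMBLED" for t in t.split(";")}
    )
    if functional_tss_ids is not None:
        unknown = set(functional_tss_ids) - set(targeted)
        if unknown:
            raise ValueError(f"functional TSSs not in library: {sorted(unknown)[:5]}")
        functional = set(functional_tss_ids)
    else:
        if n_functional > len(targeted):
            raise ValueError("n_functional exceeds number of targeted TSSs")
        functional = set(rng.choice(targeted, size=n_functional, replace=False))
    eff = {}
    tss_effect = {t: (effect_log2 if t in functional else 0.0) for t in targeted}
    for gid, tgt in zip(library.guide_id, library.target_tss_id):
        if tgt == "SCRAMBLED":
            eff[gid] = 0.0
        elif efficiency_model == "two_point":
            eff[gid] = float(rng.random() < pi)
        elif efficiency_model == "beta":
            eff[gid] = float(rng.beta(*beta_params))
        else:
            raise ValueError(f"unknown efficiency model {efficiency_model!r}")
    return SimTruth(
        functional_tss_ids=functional,
        guide_efficiency=eff,
        tss_effect=tss_effect,
        batch_offsets={r + 1: b for r, b in enumerate(batch_offsets)},
        rng_seed=rng_seed,
        params={
            "effect_log2": effect_log2, "pi": pi,
            "efficiency_model": efficiency_model,
        },
    )


def gen_screen_counts(
    library: pd.DataFrame,
    truth: SimTruth,
    depth: int = DEPTH_DEFAULT,
    sorting_stringency: float = SORTING_STRINGENCY_DEFAULT,
    sort_noise_sdlog: float = SORT_NOISE_SDLOG_DEFAULT,
    base_undiff_rate: float = BASE_UNDIFF_RATE_DEFAULT,
    abundance_sdlog: float = ABUNDANCE_SDLOG_DEFAULT,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial counts for day-0 and FACS-sorted pools.

    A guide's cells fail differentiation with probability
    q = q0*2^e / (q0*2^e + 1 - q0) where e = effect x efficiency and
    q0 = ``base_undiff_rate``; the odds-scale parametrization makes the
    expected log2 fold-change of a fully effective guide exceed the null by
    exactly ``e``. Undifferentiated pools are sequenced at
    ``sorting_stringency`` x depth (conservative gating = smaller sample);
    replicate batch offsets multiply sorted-pool depths.
    """
    rng = np.random.default_rng(rng_seed)
    gids = library.guide_id.to_numpy()
    n = len(gids)
    eff = np.array([truth.guide_efficiency[g] for g in gids])
    effect = np.array(
        [
            max(truth.tss_effect.get(t, 0.0) for t in str(tgt).split(";"))
            if tgt != "SCRAMBLED" else 0.0
            for tgt in library.target_tss_id
        ]
    )
    e = effect * eff
    q0 = base_undiff_rate
    odds = (q0 / (1 - q0)) * np.exp2(e)
    q = odds / (1 + odds)

    abundance = rng.lognormal(0.0, abundance_sdlog, size=n)
    counts = {}
    samples = []
    for rep, batch in sorted(truth.batch_offsets.items()):
        day0 = rng.multinomial(depth * n, abundance / abundance.sum())
        counts[f"day0_rep{rep}"] = day0
        samples.append({"sample": f"day0_rep{rep}", "population": "day0",
                        "replicate": rep})
        noise_u = rng.lognormal(0.0, sort_noise_sdlog, size=n)
        noise_d = rng.lognormal(0.0, sort_noise_sdlog, size=n)
        w_u = abundance * q * noise_u
        w_d = abundance * (1 - q) * noise_d
        n_u = int(depth * n * sorting_stringency * batch)
        n_d = int(depth * n * batch)
        counts[f"undiff_rep{rep}"] = rng.multinomial(n_u, w_u / w_u.sum())
        counts[f"diff_rep{rep}"] = rng.multinomial(n_d, w_d / w_d.sum())
        samples.append({"sample": f"undiff_rep{rep}",
                        "population": "undifferentiated", "replicate": rep})
        samples.append({"sample": f"diff_rep{rep}",
                        "population": "differentiated", "replicate": rep})
    counts_df = pd.DataFrame(counts, index=pd.Index(gids, name="guide_id"))
    return counts_df, pd.DataFrame(samples)


def simulate_screen_dataset(
    rng_seed: int = 0,
    n_tss: int = N_TSS_DEFAULT,
    guides_per_tss: int = GUIDES_PER_TSS_DEFAULT,
    n_scrambled: int = N_SCRAMBLED_DEFAULT,
    n_functional: int = N_FUNCTIONAL_DEFAULT,
    effect_log2: float = 1.0,
    pi: float = PI_DEFAULT,
    depth: int = DEPTH_DEFAULT,
    **count_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Library + truth + counts in one call (screen-statistics fast path).

    Returns (library, counts, samples, truth); seeds for truth and counts
    are derived from ``rng_seed`` so one integer fixes the whole dataset.
    """
    library = make_screen_library_frame(n_tss, guides_per_tss, n_scrambled)
    ss = np.random.SeedSequence(rng_seed).spawn(2)
    truth = make_sim_truth(
        library, n_functional=n_functional, effect_log2=effect_log2, pi=pi,
        rng_seed=int(ss[0].generate_state(1)[0] % (2**31)),
    )
    counts, samples = gen_screen_counts(
        library, truth, depth=depth,
        rng_seed=int(ss[1].generate_state(1)[0] % (2**31)), **count_kwargs,
    )
    return library, counts, samples, truth
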