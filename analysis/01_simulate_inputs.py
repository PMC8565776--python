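#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Builds a toy annotation containing mRNAs and lncRNAs of all four proximity
categories (six intergenic lncRNAs designated as RNA-mechanism analogues
with mRNA-like structure), a 3-lineage x 2-replicate expression table,
auxiliary feature tracks, a CRISPRi library designed from the annotation's
expressed transcripts, and FACS-sorted screen counts in which the six
RNA-mechanism lncRNA TSSs plus three other TSSs are planted as
functional (a sparse ~4% of targeted TSSs, so well-powered negatives
exist).

Writes everything under results/synthetic/ in the formats the downstream
steps consume, with the ground truth serialized next to the counts.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from lncscreen import annotation, expression, simulate
from lncscreen.io import (
    write_bed6, write_bedgraph, write_fasta_genome,
)

N_MRNA, N_LNC, N_RM = 40, 160, 6
EFFECT_LOG2, PI = 1.0, 0.5


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(args.seed).spawn(5)
    ]

    transcripts, genome = simulate.gen_annotation(
        n_mrna=N_MRNA, n_lnc=N_LNC, rng_seed=seeds[0], n_rna_mechanism=N_RM
    )
    rna_mech = sorted({t.gene_id for t in transcripts if t.gene_id.startswith("LNCRM")})
    annotation.write_gtf(transcripts, out / "annotation.gtf")
    write_fasta_genome(genome, out / "genome.fa")
    cats = annotation.categorize_all(transcripts)
    print("lncRNA category mix:", cats.value_counts().to_dict())

    expr, expr_samples, expr_truth = simulate.gen_expression(
        transcripts, rng_seed=seeds[1], rna_mechanism_ids=set(rna_mech)
    )
    expr.reset_index(drop=True).to_csv(out / "expression.tsv", sep="\t", index=False)
    expr_samples.to_csv(out / "expression_samples.tsv", sep="\t", index=False)

    tracks = simulate.gen_feature_tracks(
        transcripts, rna_mechanism_ids=set(rna_mech), rng_seed=seeds[2]
    )
    cage = tracks["cage"].assign(name=".", score=0)
    write_bed6(cage, out / "cage.bed")
    write_bed6(tracks["enhancers"], out / "enhancers.bed")
    write_bedgraph(tracks["conservation"], out / "conservation.bedgraph")
    write_bed6(tracks["endoderm_cancer_snps"], out / "endoderm_cancer_snps.bed")

    spliced = expr[~expr.is_unspliced].drop(columns="is_unspliced")
    expressed_tx = expression.expressed_set(spliced, expr_samples)
    print(f"expressed transcripts at >= 0.1 tpm: {len(expressed_tx)} of {len(spliced)}")

    library, tss = simulate.build_library(
        transcripts, genome, expressed_transcripts=expressed_tx,
        guides_per_tss=10, n_scramble_seeds=50, n_per_seed=10,
        rng_seed=seeds[3],
    )
    library.reset_index(drop=True).to_csv(out / "library.tsv", sep="\t", index=False)
    tx_gene = {t.transcript_id: t.gene_id for t in transcripts}
    tss_gene = {
        r.tss_id: sorted({tx_gene[x] for x in r.transcript_ids})[0] for r in tss
    }
    with open(out / "tss_gene.json", "w") as fh:
        json.dump(tss_gene, fh, indent=0, sort_keys=True)
    print(f"library: {len(tss)} TSSs, {library.shape[0]} unique guides "
          f"({int(library.is_control.sum())} scrambled)")

    # plant the six RNA-mechanism lncRNA TSSs plus six others as functional
    gene_tss = {g: t for t, g in tss_gene.items()}
    rm_tss = {gene_tss[g] for g in rna_mech if g in gene_tss}
    rng = np.random.default_rng(seeds[4])
    others = sorted(set(tss_gene) - rm_tss)
    functional = rm_tss | set(rng.choice(others, size=3, replace=False))
    truth = simulate.make_sim_truth(
        library, effect_log2=EFFECT_LOG2, pi=PI, rng_seed=seeds[4],
        functional_tss_ids=functional,
    )
    counts, screen_samples = simulate.gen_screen_counts(
        library, truth, rng_seed=seeds[4]
    )
    counts.reset_index().to_csv(out / "counts.tsv", sep="\t", index=False)
    screen_samples.to_csv(out / "screen_samples.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
    with open(out / "rna_mechanism_genes.json", "w") as fh:
        json.dump(rna_mech, fh)
    print(f"screen: {counts.shape[0]} guides, {len(functional)} functional TSSs "
          f"(effect {EFFECT_LOG2} log2, guide efficiency {PI})")


if __name__ == "__main__":
    main()
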