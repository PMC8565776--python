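# lncscreen

Analysis toolkit for pooled CRISPRi screens of lncRNA loci during directed
differentiation of human embryonic stem cells.

In this screen design, hESCs expressing dCas9-KRAB are transduced with a
genome-wide sgRNA library targeting lncRNA transcription start sites, induced
to differentiate into definitive endoderm, and FACS-sorted into
differentiated (FOXA2+/SOX17+) and undifferentiated (double-negative)
populations. A locus whose knockdown blocks differentiation shows guide
enrichment in the undifferentiated pool. The computational challenges this
package addresses are (i) designing the library from an annotation whose
lncRNA TSSs are unreliable, (ii) calling hit loci from noisy sorted counts
where only a subset of each locus's guides actually work, and (iii) inferring
which hit lncRNAs act through RNA-based (rather than DNA/enhancer-based)
mechanisms from genomic features.

## What it implements

**Annotation & library design** — lncRNA classification by genomic context
(promoter-overlapping > transcript-overlapping > gene-nearby > intergenic,
1-kb rules, in that precedence); TSS reassignment by a three-rule fallback
(curated TSS, else closest same-strand CAGE cluster within 400 bp, else the
annotated 5' end); TSS consolidation; top-10 guide selection from pre-ranked
candidates; scrambled negative controls (letter permutations of 500 sampled
guides x 10, rejecting exact genome matches); sequence deduplication.

**Expression profiling** — 0.1-tpm expression thresholding; the tau
tissue-specificity statistic across *n* lineages,

&nbsp;&nbsp;&nbsp;&nbsp;τ = Σᵢ (1 − x̂ᵢ) / (n − 1),  x̂ᵢ = xᵢ / maxⱼ xⱼ,

with τ = 0 for ubiquitous and τ = 1 for single-lineage expression; rank-sum
comparisons between biotypes; and a clearly-flagged plumbing DE test for
synthetic data.

**Screen statistics** — counts-per-million; the three-stage filter cascade
(cpm ≥ 5 in both day-0 replicates → cpm ≥ 1 in both undifferentiated
replicates → target TSS retains ≥ 3 surviving guides, scrambled guides
exempt); replicate-paired enrichment log2((u+c)/(d+c)) on median-of-ratios
normalized counts; hierarchical-mixture hit calling with an empirical null
fit to scrambled guides — each TSS is functional with prior *p* and,
conditional on that, each guide is effective with probability π, effective
guides drawing from a shifted normal; EM fit, per-TSS posterior null
probability, and a global FDR by the q-value convention (running mean of
posterior null probabilities in score order). Hits are FDR < 0.1; stringent
non-hits (well-powered negatives) have FDR > 0.9 with ≥ 9 filtered guides.
Effect sizes are the mean of a TSS's top-3 guide log2 fold-changes.
Downstream: per-feature Mann-Whitney comparisons with BH correction, Fisher
association of hit status with differential expression, and validation
scoring of individually tested guides.

**Mechanism clustering** — 11 genomic features per gene (transcript length,
exon count, GC, locus length, nearby CAGE TSSs, enhancer counts/distance,
TSS and exon conservation, maximum expression, splicing efficiency),
standardized and clustered with k-means (k = 2); the cluster dominated by
mRNAs is labeled, and hit lncRNAs inside it are predicted to act through
RNA-based mechanisms (the pattern followed by XIST, NEAT1, and MALAT1).

**Synthetic screen generator** — produces all of the above inputs with
serialized ground truth: toy annotations realizing an exact category mix,
lineage-structured expression with known tau and splicing efficiency, and
multinomial sorted counts with planted functional TSSs, variable per-guide
efficiency, conservative undifferentiated gating, and replicate batch
offsets.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (seeds fixed; outputs under `results/`):

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_profile_expression.py
python analysis/03_screen_hit_calling.py --seed 1
python analysis/04_features_and_clustering.py --seed 42
python analysis/05_calibration_suites.py --seed 1
```

Output of steps 02–04 (abridged):

```
tau medians: lncRNA 0.979 vs mRNA 0.222 (rank-sum p = 6.48e-06)
filter cascade: {'input_guides': 2230, ..., 'after_stage3_min_guides': 2230, 'tss_after_stage3': 173}
mixture fit: null N(-0.041, 0.504), alt N(1.04, 0.44), pi = 0.38, prior p = 0.082
calls: 9 hits at FDR < 0.1 (6/9 planted recovered, FDP 0.33); 31 stringent non-hit TSSs
features separating hits from stringent non-hits (BH FDR < 0.10): ['locus_length',
  'max_exon_count', 'max_transcript_length', 'n_enhancers_1mb', 'splicing_efficiency',
  'tss_conservation_200bp']
k-means (k=2): 46 genes in the mRNA-like cluster; 3 hit lncRNAs predicted to act
  through RNA-based mechanisms: ['LNCRM0156', 'LNCRM0157', 'LNCRM0158']
```

Reading this: the generator planted lineage-specific lncRNAs (hence the tau
gap), nine functional TSSs among 173 (six of which are recovered at
FDR < 0.1; with guide efficiency 0.5 and a +2-SD effect, partial sensitivity
is expected), and six lncRNAs with mRNA-like profiles; the hit ∩ mRNA-like
intersection correctly returns only planted RNA-mechanism analogues.

Step 05 measures calibration at the default study scale (1,000 TSSs × 10
guides, 50 seeds):

```
pure null: mean FDP 0.080 at nominal 0.1 (mean 0.12 false hits/dataset)
planted: median sensitivity 0.74, median FDP 0.096 (effect 1.00 log2 = 2 x null SD 0.502)
estimators at 500 reads/guide: enrichment bias -0.076 log2, top-3 effect-size bias -0.048 log2
```

A CLI mirrors the drivers for file-based use:
`lncscreen simulate-screen | design-library | profile-expression |
screen-call | mechanism-cluster | run-all` (see `--help`).

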