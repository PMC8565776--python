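# Methods

This note documents the models, estimators, and numerical choices behind
`lncscreen`, and what the synthetic-data tests do and do not establish.

## Coordinates and annotation handling

GTF input is 1-based inclusive; all internal interval arithmetic is 0-based
half-open (pyranges performs the conversion on read); BED/bedGraph output is
0-based half-open. Point coordinates (TSS positions, CAGE clusters) are
reported 1-based to match GTF.

lncRNA categorization applies four rules in a fixed precedence —
promoter-overlapping (transcription start within 1 kb of a protein-coding
gene start), transcript-overlapping (physical transcript overlap),
gene-nearby (a protein-coding gene edge within 1 kb of the lncRNA gene
edge), intergenic (default) — so the categories partition the lncRNA set. A
gene satisfying several rules takes the first. Two senses of "gene start"
coexist in this field's usage; we resolve them explicitly: the promoter rule
compares strand-aware transcription start positions (configurable to
strand-agnostic genomic starts via `promoter_rule_partner="gene_start"`),
while the gene-nearby rule uses strand-agnostic genomic min/max edges.

TSS assignment is a three-rule fallback: an explicitly curated TSS wins;
else the closest same-strand CAGE cluster within 400 bp of the annotated 5'
end; else the annotated 5' end. Equidistant CAGE clusters break toward the
5'-most position on the transcript's strand, making assignment
deterministic.

## Library assembly

Guide scoring and ranking are consumed from input (an external designer
produces per-TSS candidate ranks); the package selects the top 10 per TSS,
consolidates TSSs by exact coordinate identity, and deduplicates guides by
sequence with target-set union. Scrambled controls permute the letters of
500 sampled targeting guides 10 times each; any permutation with an exact
substring match to the genome (either strand) is rejected and re-drawn, so
the quota of 5,000 controls is met post-filtering. The exact-match criterion
stands in for a permissive alignment filter: at toy-genome scale it is the
only deterministic, well-defined analogue. Seeds with fewer than two
distinct letters cannot be permuted non-identically and are replaced with a
warning; rejection sampling is guarded by a 1,000-iteration cap.

## Expression statistics

Replicates are averaged per lineage before both expression thresholding
(≥ 0.1 tpm in ≥ 1 lineage; an any-sample mode exists) and tau. Gene-level
tpm is the exact sum of transcript tpm. tau is scale-invariant, bounded in
[0, 1], and undefined (NaN) for genes silent in every lineage.

Splicing efficiency of a gene is sum(spliced tpm)/(sum(spliced tpm) +
unspliced tpm), where the unspliced pre-RNA is quantified as an additional
"transcript"; 0 means fully unspliced signal, 1 fully spliced, NaN when the
gene is silent.

The built-in differential-expression test exists only so synthetic
pipelines run end-to-end; real screens consume externally computed
q-values. It is a t-test on log2(tpm + 0.01) whose residual variance is
pooled across all transcripts, with BH correction. The pooled design is
deliberate: with two replicates per lineage, a per-transcript Welch test
has ~1 degree of freedom and essentially no power at any effect size,
whereas the synthetic generator is homoskedastic on the log scale, where
pooling is exact. On heteroskedastic real data pooling would be
anticonservative — one reason this test is labeled plumbing in every output
row (`method = pooled_t_plumbing_not_screen_de`). Zero-variance transcripts
get p = 1 with a flag.

## Screen statistics

**Filtering.** Three consecutive filters remove noisy guides: cpm ≥ 5 in
every day-0 replicate (poor initial representation), cpm ≥ 1 in every
undifferentiated replicate (conservative FACS gating leaves low-count
dropouts), and ≥ 3 surviving guides per targeted TSS (hit calling needs
within-TSS replication). Thresholds are inclusive (≥, exact boundary kept);
cpm uses raw library size because filtering precedes modeling. Scrambled
guides have no TSS and bypass the third filter; their "filtered" count is
defined by the first two stages.

**Enrichment.** Per-guide enrichment is a replicate-paired normalized log
ratio: size factors by median-of-ratios across the sorted samples only, then
per replicate log2((undiff + c)/(diff + c)) with pseudo-count c = 0.5,
averaged over replicates, with a between-replicate standard error. Pairing
within replicate blocks batch effects the way a batch covariate in a
negative-binomial count GLM would, while remaining deterministic and exactly
analyzable; simulations verify the estimator recovers planted effects within
0.1 log2 units at 500 reads/guide. Positive log2FC means enrichment in the
undifferentiated pool, i.e. the knockdown impairs differentiation; the sign
convention is verified end-to-end by planting drop-out effects.

**Hit calling.** The hierarchical mixture models guide-level log2FC x for
each TSS g:

    L_g = p · Π_i [π f1(x_i) + (1−π) f0(x_i)] + (1−p) · Π_i f0(x_i)

f0 is the empirical null — a normal fit to filtered scrambled guides
(moment fit; a median/MAD robust option exists), carrying the screen's full
technical noise without biology. p (prior fraction of functional TSSs), π
(per-guide efficiency), and the alternative f1 = N(μ1, σ1) are fit by EM
with the null fixed: tolerance 1e-6 on the log-likelihood, ≤ 500
iterations, 5 seeded restarts, best likelihood kept, non-convergence
flagged. Guides of a functional TSS are a π/(1−π) mixture of shifted and
null draws — the "only a subset of guides work" structure.

Two identifiability constraints keep the alternative a genuine drop-out
component: μ1 ≥ μ0 + 0.5σ0 (it is a *shifted* component; the model's
premise is that most targeting guides resemble controls) and σ1 ≥ 0.5σ0
(effective guides experience at least the screen noise). Both were
motivated by pure-null diagnostics: with a free location a centered broad
component can absorb sampling fluctuations of the empirical-null scale
(observed: μ1 ≈ 0.05σ0, p ≈ 0.7, 23 false hits on one null dataset), and
with a free scale a needle-width component can fit the null's extreme tail.
With the constraints, pure-null mean FDP is 0.04–0.08 at nominal 0.1 across
seed sets, and planted sensitivity is unchanged.

The global FDR of a TSS is the running mean of posterior null probabilities
in decreasing-score order (q-value convention), ties sharing their group's
worst value. Hits: FDR < 0.1. Stringent non-hits: FDR > 0.9 with ≥ 9
filtered guides — well-powered negatives for feature comparisons; one TSS
per gene is flagged for gene-level lists. Note the convention caps the
maximum FDR at the mean posterior null over all TSSs, so stringent non-hits
can only exist when hits are sparse (true of real screens at ~1% functional;
the synthetic narrative run plants ~5%).

**Effect size** is the mean of a TSS's 3 largest guide log2FCs (NaN below
3 guides). When a TSS has more guides than 3, this published definition
carries a known order-statistic lift under noise (top-3 of 10 null guides
averages ≈ +1.0 null SD); the unbiasedness check therefore uses 3-guide
TSSs, where the statistic reduces to a plain mean and is selection-free.

**Validation scoring** of individually tested guides is
log2[(u/d)/(u_scr/d_scr)] against a scrambled control measured in the same
batch, with empty FACS gates floored at 0.1% (warned). The published
formula exists only as a figure graphic, so this default lives in one
switchable function.

**Downstream tests** use scipy (Mann-Whitney two-sided, Fisher exact) and
statsmodels (BH); the test suite checks both against exhaustive enumeration
oracles on small instances. The Fisher odds ratio defaults to the sample
OR ad/bc (conditional MLE available), NaN on zero margins.

## Mechanism clustering

Features are scaled to mean 1, sd 1 (population sd — fixed by convention
since either choice is defensible); k-means over Euclidean distances is
invariant to the shared translation, so this equals z-scoring. Constant
features are dropped with a warning; missing values are imputed at the
post-standardization mean (= 1) and flagged. k-means uses k-means++
initialization with 10 restarts under a fixed seed; on instances small
enough to enumerate every 2-partition it attains the exact optimum. Labels
are canonicalized so cluster 2 is the mRNA-majority cluster; `mrna_like` is
membership there, and candidate RNA-mechanism hits are screen-hit lncRNAs
with `mrna_like = True`. Gold-standard placement (XIST/NEAT1/MALAT1
analogues) is a reported diagnostic, never an input to labeling. t-SNE is
visualization only; no decision or assertion depends on it beyond finite,
seed-deterministic coordinates.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions under which all calibration claims hold.

*Annotation*: protein-coding genes (4–8 kb, 3–5 exons) spaced 50 kb apart
on a toy chromosome; lncRNAs placed to realize a requested category mix
exactly (divergent at −300 bp for promoter-overlapping, sense within the
gene body for transcript-overlapping, 300 bp past the 3' end for
gene-nearby, own slots for intergenic). Designated RNA-mechanism lncRNAs
(`LNCRM*`) get mRNA-like structure; a matched-structure mode gives *all*
lncRNAs mRNA-like structure so that clustering separation can be attributed
to splicing efficiency, maximum expression, and exon conservation alone
(ablating those three then collapses separation to chance — asserted in
tests).

*Expression*: lineage-specific genes put ~98% of expression in one lineage
(tau ≈ 1), ubiquitous genes are near-flat; 70% of lncRNAs and 30% of mRNAs
are specific by default, reproducing the lncRNA specificity excess.
Replicate noise is lognormal at CV 10%. Splicing ground truth (mRNA-like
0.75–0.98, lncRNA-like 0.05–0.55) is realized through an unspliced
pseudo-transcript per gene; the estimate recovers it exactly at zero noise
and to ~0.01 mean absolute error at default noise (the tolerance asserted
is mean |error| ≤ 0.05; individual low-expression genes can deviate more).

*Screen counts*: each guide has a lognormal abundance (sd 0.5 log units);
day-0 counts are multinomial at 500 reads/guide. A cell fails
differentiation with probability q where the odds q/(1−q) equal the
baseline odds (q0 = 0.2) times 2^e, e = TSS effect × guide efficiency —
the odds-scale construction makes a fully effective guide's expected log2FC
exceed the null by exactly e. Guide efficiency is a two-point mixture
(effective with probability π = 0.5) by default; a Beta option exists.
Sorting noise is lognormal (sd 0.35 log units per guide/pool/replicate),
giving an empirical null SD ≈ 0.5 log2 units; undifferentiated pools are
sequenced at half depth (conservative gating) and replicate 2 carries a
×0.7 batch offset on sorted-pool depths. Ground truth (functional TSSs,
per-guide efficiencies, effects, batch offsets, seeds) is serialized next
to every count table.

What these simulations do *not* capture: guide-specific cutting/silencing
biology, chromatin context, off-target effects, growth-phenotype
confounding, overdispersion beyond lognormal×multinomial, and any real
correlation structure among the 11 features. Passing calibration here shows
the statistics are correct under the assumed noise model, not that the
model captures every property of a real screen.

## Problem sizes and determinism

Calibration suites run 50 seeds of 1,000 TSSs × 10 guides (+1,000 scrambled)
and 200 estimator replicates — sizes chosen so the whole suite completes in
a few minutes on one CPU while leaving Monte-Carlo error well below the
asserted margins. The planted effect is defined as 2 × the empirical null SD
measured from a same-settings null run, not a hard-coded log2 value. Every
random draw flows from explicit integer seeds (numpy `SeedSequence` spawning
for sub-streams, all below 2³¹); reruns are byte-identical, which the tests
assert on GTF, count, and result files.

## Known limitations

* The supplementary-table reproduction requires the released tables (not
  redistributable here); its loaders accommodate the published column
  layouts but were written against the described schema, not run against
  the originals in this environment.
* The q-value-style FDR is slightly conservative in dense-signal regimes
  and undefined above the mean posterior null (see stringent non-hit note).
* The empirical null assumes scrambled guides share the targeting guides'
  technical noise; guide-composition effects that violate this would bias
  the FDR in either direction.
* The validation-score definition is provisional pending the exact
  published formula.
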