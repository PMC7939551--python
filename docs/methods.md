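# Methods

This note documents the statistical models behind `hemapriming`, the
defaults that matter, what the synthetic cohorts do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Balanced-subsampling differential expression

Two cell groups of unequal size are compared by subsampling the larger
group to the smaller group's size. Each of *n*<sub>reps</sub> repetitions
(default 1001) is summarized by the median, over genes, of two-sided
unequal-variance (Welch) *t*-test p-values; the representative subsample is
the repetition whose median equals the median of the repetition medians.
*n*<sub>reps</sub> is forced odd so that the median of medians is an
attained value and the selection is well defined; ties among repetitions
attaining it are broken by the lowest repetition index. Equal-size groups
skip subsampling entirely — the procedure exists only to balance unequal
groups. The per-repetition median is taken over genes expressed in at least
one cell of the union of the two compared sets, because all-zero genes have
an undefined *t* statistic; genes with zero variance in both groups
contribute p = 1 rather than NaN.

On the selected balanced pair, each gene receives a two-sided Wilcoxon
rank-sum p-value with Benjamini-Hochberg adjustment across all tested
genes. The BH step-up is implemented in-package with plain p·n/rank
arithmetic so adjusted values are bit-reproducible; it agrees with
statsmodels to floating-point noise. The fold change is
log₂[(expm1(x̄_A)+1)/(expm1(x̄_B)+1)] on the lognorm layer with a +1
pseudocount — the convention of mainstream scRNA toolkits, adopted because
no formula is otherwise forced by the procedure. The keep-filter retains
genes expressed (count > 0) in ≥ 30% of the cells of at least one group;
the out-group cap (default 1) and fold-change floor (default 0) are
configurable no-ops at their defaults. The membrane variant restricts the
matrix to a supplied gene list before both stages; it performs no database
queries.

## Organ test batteries

**Composition.** Cells are restricted to FACS gates present in both organs
(matched gates). Within each (gate, organ) the per-cluster counts are
scaled to sum to 100; each (cluster, organ) is then summarized by the
median over gates. Because χ² and Fisher tests need counts, each organ's
median vector is rescaled to that organ's true matched-gate cell total and
rounded half-to-even — a fixed, deterministic rule; the global test is a
χ² of homogeneity on the resulting 2 × K table and each cluster is then
tested with Fisher's exact test on (cluster vs rest) × (liver vs femur).

**Expressed-gene counts.** Each cell contributes n_genes / mapped_reads
(expressed genes per uniquely mapped read), removing depth effects. Per
cluster, both a KS and an MWW two-sided test compare liver and femur; the
larger group is subsampled to the smaller group's size over the configured
repetitions and the median p (and median statistic) is reported; equal
sizes skip subsampling. Clusters with fewer than 20 cells in either organ
are skipped with a log record.

**Cell cycle.** Per cluster, cycling (G2M and S pooled, since the upstream
phase caller emits only G1/S/G2M) is compared against G1 between organs
with Fisher's exact test; G0 cells are excluded. Each organ's
(cycling, G1) pair is rescaled to a common total — the rounded mean of the
two organ cell counts — with G1 taken as the complement so the margins
stay exact.

All batteries report the four-level significance bin
[0, 0.01] → 0, (0.01, 0.05] → 1, (0.05, 0.1] → 2, (0.1, 1] → 3; binning is
exhaustive and mutually exclusive on [0, 1].

Exact conditional tests are inherently conservative: at 2 × 2 tables with
margins around 100–4000 the attained size of Fisher's exact test is
roughly 0.036–0.041 at nominal 0.05. The type-I validation in the test
suite measures empirical rejection rates against the nominal level; small
shortfalls of this magnitude are a property of the exact test, not of the
pipeline.

## Regulon accessibility

Targets of the analyzed TF are kept at importance strictly greater than 4
(descending importance, name-ordered ties). Promoter peaks overlap
[TSS − 3 kb, TSS + 3 kb); enhancer peaks overlap [TSS − 50 kb, TSS + 50 kb)
but not the promoter window of that same gene and must carry a motif hit
for the TF. All coordinates are 0-based half-open; a peak may serve several
genes. Scoring: per cell, the open-peak count of each gene's region is
divided by the cell's total open peaks (the only depth available for a
binary matrix), min-max scaled across the gene set within the cell
(constant vectors map to 0 so heatmaps never see NaN), then averaged per
cluster; scores therefore lie in [0, 1]. Heatmap rows are ordered by
k-means with 5 centroids (deterministic under seed, clusters sorted by
descending centroid mean). The paired expression panel is the per-cluster
mean lognorm of the same genes, min-max scaled per gene.

Co-accessibility: per cell and lineage marker set, the indicator is 1 when
any promoter peak of any gene in the set is open; a per-lineage indicator
matches a three-bar lineage-pair layout, whereas a per-gene-pair
construction would produce one bar per gene pair. Each lineage pair gives
a 2 × 2 table over the cluster's cells, a two-sided Fisher exact p on the
raw table, and the sample odds ratio with a Haldane–Anscombe 0.5 correction
applied (and flagged) only when some cell of the table is zero.

## Label transfer

The query representation is gene activity: binary peaks summed over
[body_start − 3 kb, body_end + 3 kb), clamped at the chromosome origin,
depth-normalized to 10,000 per cell and log1p-transformed — deliberately
the same normalization as the RNA side. Reference clusters with at least
20 cells define the classes. Shared genes are z-scored on the reference;
each query cell is Pearson-correlated with each class centroid and the
correlations pass through a softmax at temperature 0.2 to give a score
simplex. The temperature was chosen so the scores behave like class
probabilities at the 0.40 decision threshold with six classes: at
temperature 1 a query cell lying exactly on a well-separated centroid
scores ≈ exp(1)/(exp(1)+5·exp(−0.2)) ≈ 0.399 and would be rejected, while
very small temperatures amplify correlation noise in uniform-mixture cells
above the threshold; 0.2 keeps confident assignments well above 0.40 and
mixtures near 1/K on both sides. Cells below the threshold are labeled
`unclassified`. The centroid classifier is a deliberately simple,
documented backend isolated behind one operation; an anchor-based transfer
could be swapped in without touching the gene-activity representation or
the thresholding semantics, which are the substance here.

## Synthetic cohorts

The RNA model draws counts from a negative binomial with gene-level
dispersion α (var = μ + αμ², default α = 0.5) — adequate for full-length
(Smart-seq2-like) counts at this scale; zero inflation is not modeled.
Background gene means are lognormal around the base mean (default 2);
marker genes are pinned at the base mean and multiplied by 2^log2fc in
their own cluster, which gives a closed-form expected fold change for
validation. Organ compositions are sampled multinomially with the
configured per-cluster weights as expected counts — without this sampling
step a null cohort has *no* composition noise and every composition test
degenerates to p = 1. Mapped reads are proportional to the cell's total
count with lognormal noise (σ = 0.1); a femur-side factor
(1 + organ_gene_count_shift) plants expressed-genes-per-read differences.
Cycle phases are drawn per (cluster, organ) from a (G1, S, G2M) simplex,
default (0.6, 0.25, 0.15).

The ATAC model is Bernoulli per peak and cell (downstream analysis only
ever sees binarized matrices): one promoter peak per gene inside TSS ± 3 kb,
one enhancer peak inside TSS ± 50 kb but outside ± 3 kb of every TSS, and
background peaks on a gene-free chromosome. Marker-gene promoters open
with an elevated probability in their own cluster. Planted
co-accessibility uses a shared latent Bernoulli: each of the two promoter
states copies a common Bernoulli(q) draw with probability ρ and is an
independent Bernoulli(q) otherwise, giving correlation ρ² and the
closed-form odds ratio implemented in
`expected_coaccess_odds_ratio` — chosen precisely because the expectation
is available in closed form for validation. The simulated regulon's target
importances straddle the selection threshold of 4 by construction.

A single integer seed drives every draw through a splittable
`SeedSequence`; identical configs give identical cohorts byte for byte.

What the cohorts do **not** emulate: read-level noise, fragment-length and
TSS-enrichment structure, doublets, batch effects, zero inflation,
gene–gene correlation beyond the planted structure, and realistic gate
biology (gates are mixed independently of organ by default). Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated models, not robustness to every artifact of real data.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use desk-scale cohorts
chosen to make each check informative: type-I error on 40-cluster null
cohorts with 100 cells per organ and cluster; power on 500 cells/organ
(3× composition shift), 150 vs 100 cells (20% gene-count shift) and 300
cells/organ (50% vs 30% cycling); DE recovery on 300 vs 200 cells with 101
subsampling repetitions; co-accessibility on 500 cells; transfer on six
60-cell reference clusters with 50 query cells each plus 30
uniform-mixture cells. The subsampling default of 1001 repetitions is kept
for the CLI, while validation uses 101 — the selection rule is identical
and its exactness is checked separately.

## Known limitations

- The rescale-and-round rule that turns normalized abundances back into
  counts is this package's choice; other roundings would shift per-cluster
  Fisher p-values slightly.
- The median-of-p over subsamples is exactly calibrated only when group
  sizes are equal (where it reduces to a single test); under strong
  imbalance the repetition p-values are correlated and the median is
  mildly conservative.
- The label-transfer score is a softmax over centroid correlations, not an
  anchor-weighted class probability; only the thresholding semantics are
  comparable with anchor-based pipelines.
- Dense in-memory matrices cap practical size at roughly 10⁴ cells ×
  10⁴ features.
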