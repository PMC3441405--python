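# Methods

This note documents the models and numerical choices behind `uncoupling`,
what the synthetic data generator does and does not emulate, and the
known limitations of each statistic.

## Data model and preprocessing

A paired expression set holds four log2-intensity matrices — two RNA
levels (transcriptome = total mRNA, translatome = polysomal mRNA) × two
conditions (control, treated) — over one shared feature universe, with at
least two replicate arrays per group and optional per-array present/absent
detection calls.

**Low-signal filtering** removes a feature only when, within *every* one
of the four level-condition groups, the fraction of arrays calling it
absent exceeds `majority_fraction` (default 0.5, a strict majority). The
per-group AND is deliberate: a feature reliably detected in any group
carries signal for the cross-level comparison. Without detection calls the
filter passes through with a logged warning.

**Quantile normalization** maps every array onto the reference
distribution of rank-wise cross-array means and is applied jointly across
all arrays of all four groups, so that fold changes are comparable across
levels. Tied input values receive the mean of their tied positions'
reference values. Consequences worth knowing: tie-free columns share one
sorted vector exactly (and the operation is idempotent); with ties, equal
column *sums* are preserved instead. Input intensities are assumed
already log2; a flag log2-transforms linear inputs.

**Probe collapse** averages probe rows mapping to the same gene
(arithmetic mean, matching the averaging convention of the downstream
mean-difference fold change, with which it therefore commutes); a probe
mapped to two genes is an error, unmapped probes are dropped and counted.

## Rank-product differential expression

For a comparison with n_c control and n_t treated replicates, every one of
the K = n_c·n_t replicate pairings yields a fold-change vector; genes are
ranked within each pairing (rank 1 = strongest change in the tested
direction, average ranks on ties) and the statistic is the geometric mean
of a gene's K ranks. Up- and down-regulation are two separate one-sided
analyses combined per gene by the smaller pfp, with the direction taken
from that argmin. The unpaired all-pairings variant was chosen because the
replicate structure of two-group microarray designs rarely justifies a
paired reading.

The **pfp** (percentage of false prediction) at a gene with observed rank
product v and rank position r is `E[#permuted RP ≤ v] / r`, with a
cumulative-max pass in rank order so pfp is monotone. Two permutation
nulls are implemented:

- `scheme='array'` (default): gene labels are shuffled independently
  within each sample array and all K pairings are recomputed. Pairings
  that share an array are rank-correlated (~0.5 for equal-variance
  noise), and this null preserves that structure. On pure-noise data
  ~1% of genes fall below pfp 0.2.
- `scheme='ranking'`: gene labels are shuffled independently within each
  of the K rankings. This stricter independence null ignores the
  shared-array correlation and is anti-conservative for the all-pairings
  statistic (~15% of pure-noise genes below pfp 0.2); it is retained
  because it is exhaustively enumerable, which gives an exact brute-force
  oracle for the estimator on tiny instances (`exhaustive=True`).

Known behavior of the pfp (both schemes): because the permutation universe
is all-null, the estimate becomes very conservative when a large fraction
of genes is truly differential (the true positives crowd the top ranks
that the null is compared against). At the few-percent DEG densities of
replicated microarray comparisons this effect is negligible; at ~50% DEG
density recall at pfp < 0.2 drops to ~0.5. In the fully tied noiseless
limit, unchanged genes share a single rank product and a positive constant
pfp (~0.7 on the fixtures used), so exact planted recovery holds at the
working threshold 0.2 but not at arbitrarily large thresholds.

The alternative caller is a pooled-variance two-sample t-test with
Benjamini–Hochberg step-up. Genes with zero variance in both groups get
p = 1 when the means are equal; otherwise the pooled variance is floored
at 1e-12 (logged), which drives a genuine mean shift toward p = 0.

## Coupling classes and buffering

A gene significant at both levels is coupled if the two calls are
homodirectional, antidirectional otherwise; significant at exactly one
level, it is transcriptome-only or translatome-only; significant nowhere,
unchanged. Direction comes from the caller's per-gene direction rather
than the fold-change sign when the two disagree (logged). Summary
percentages are over DEGs (unchanged excluded); with zero DEGs the
percentages are explicit `None` rather than 0 — the denominator convention
materially changes small-count percentages, so both counts and
percentages are always reported together. Translational
enhancement/buffering uses strict comparisons of the translatome vs
transcriptome fold change; exact ties are counted separately. Its default
scope is the DEG union; a flag widens it to all genes.

## Enrichment and ontology semantics

Term enrichment is the one-sided hypergeometric tail P(X ≥ k) with the
universe set to all genes surviving expression filters (the measured
background), BH step-up at FDR 5%. An EASE-style variant (overlap reduced
by one) is available behind a flag and off by default. Percentages in
overlap summaries are integer-rounded half away from zero, matching how
such tables are conventionally printed.

Pairwise term similarity is the Wang-style aggregate: each term
contributes an S-value to every ancestor — the maximum over upward paths
of the product of edge weights (`is_a` 0.8, `part_of` 0.6, configurable) —
and similarity is the sum of both terms' S-values over common ancestors
divided by the sum over all ancestors. The measure depends only on the
graph, not on annotation corpora, which keeps it free of annotation bias;
information-content measures are deliberately out of scope. Cross-
namespace pairs contribute similarity 0 inside the specificity statistics
(an error if compared directly).

Semantic specificity of a translatome list (m terms) against a
transcriptome list (n terms) is one minus the mean over the m terms of
each term's maximum similarity to the other list (and symmetrically with
divisor n). Identical lists give 0 and 0; an empty list makes the
statistic undefined and the result carries an explicit reason instead of
a number. Reference distributions compare, for each dataset, the
one-sided specificity of its transcriptome list against every other
dataset's transcriptome list; the observed within-pair value is placed
descriptively (below median / below minimum) — no p-value is invented for
this comparison. GOslim roll-ups compute per-term transcriptome and
translatome specificity degrees (level-specific enrichment count over
total enrichment count across datasets), take medians per slim category,
and sort categories by the degree difference.

## Independence tests

With N measured genes, n1 and n2 DEGs per level and observed overlap k:

- **Likelihood ratio**: the two counts are modeled as independent
  binomials; the null shares one proportion p0 = (n1+n2)/(2N), the
  alternative fits each level's own proportion; G = 2(ℓ1−ℓ0) is referred
  to chi-square with 1 df. This is the simplest model for "are the DEG
  numbers the same at both levels"; it says nothing about which genes
  overlap.
- **Random overlap**: n1- and n2-gene subsets are drawn without
  replacement from the N-gene universe (the measured-gene population, not
  the DEG union, where overlap would be ill-defined) and the overlap is
  recorded; p = (#{overlap ≥ k} + 1)/(n_iter + 1). The add-one correction
  keeps p strictly positive. The exact hypergeometric upper tail is
  implemented separately as the closed-form oracle; the bootstrap
  deliberately samples subsets rather than the hypergeometric
  distribution so the two routes stay independent.
- **Mutual information**: plug-in MI in bits (log2, 0·log 0 = 0) of the
  2×2 table of binary DEG indicators. Bits were chosen because the
  reported magnitudes at typical DEG frequencies are natural on that
  scale. The feasibility maximum is the MI of two completely overlapping
  lists of size ⌊(n1+n2)/2⌋, i.e. the binary entropy H(⌊(n1+n2)/2⌋/N);
  the feasibility minimum is the exact minimum of the plug-in MI over all
  realizable overlaps k ∈ [max(0, n1+n2−N), min(n1, n2)] — attained near
  the independence overlap n1·n2/N and exactly 0 when that is an integer.
  (The zero-overlap table, sometimes used as the "minimum", exceeds this
  true bound whenever n1·n2/N is well above zero, and observed MI on
  independent labels then falls below it; the exact minimum is what makes
  `mi_min ≤ MI ≤ mi_max` an invariant.) The bootstrap null redraws the
  gene assignments with both counts fixed; the midrange position is
  (MI−min)/(max−min), `None` when the range is degenerate.

All bootstrap p-values use the same subset-resampling machinery and seeds
derived from the run seed, so a pipeline run is byte-reproducible.

## Synthetic data generator

The generator emulates a replicated two-group log2-intensity design
profiled at both RNA levels: per-gene baselines uniform in log2 space
(default 6–14, the dynamic range of a typical intensity microarray),
iid Gaussian replicate noise (default sd 0.3 log2 units), and planted
signed effects of constant magnitude (default 2.0) whose sign is random
per gene unless pinned. Planted class counts follow the requested
fractions exactly via largest-remainder rounding, so recovery tests
measure the caller, not the generator's sampling noise; truth labels
record the planted effects, not post-hoc significance.

The default class mix is sparse and balanced — 2.5% of genes in each of
the four DEG classes, 90% unchanged — giving per-level DEG fractions of
7.5%, in line with the few-percent DEG fractions of the replicated
microarray comparisons this emulates. Equal weights for the four classes
were chosen so every class is exercised equally by recovery tests; the
fraction mapping is fully configurable for asymmetric scenarios (e.g. a
translatome-dominated mix).

What the generator does *not* simulate: probe-level spatial artifacts,
dye or scanner effects, array-level intensity biases, heteroscedastic or
heavy-tailed noise, and correlated gene modules. Two practical
consequences. First, passing recovery tests demonstrate correctness of
the statistical machinery under the stated noise model, not robustness to
real microarray artifacts. Second, since no array-level bias is planted,
quantile normalization has nothing to correct on synthetic data and only
compresses planted effects for genes near the dynamic-range edges (the
extreme order statistics are remapped toward the pooled reference); the
parameter-recovery checks therefore run the pipeline with normalization
disabled, while normalization remains on by default for real inputs and
is verified by its own unit and property tests.

Toy ontologies are rooted DAGs: a branching-factor tree plus occasional
extra parents, edges mostly `is_a` with some `part_of`, every term
annotating at least one gene, all deterministic under the seed. The slim
mapping sends each term to its depth-1 ancestor along the primary tree.

## Problem sizes and defaults

Default analysis parameters mirror the working conventions of the field:
pfp threshold 0.2, enrichment FDR 0.05, permutations 1000 (500 in the
bundled end-to-end runs), bootstrap iterations 10^5 in the acceptance
script with a 10^6 default in the CLI `independence` command. The
end-to-end recovery checks use 2000 genes × 3 replicates, effect 2.0,
noise sd 0.3 — effect/noise chosen so planted DEGs are clearly but not
trivially separable (FC standard error ≈ 0.245, i.e. ~8 sd per effect).

## Known limitations

- The pfp is an expected-false-prediction ratio, not a strict FDR; its
  conservativeness grows with the true DEG fraction (see above).
- The LRT treats the two levels' DEG counts as independent binomials,
  ignoring that both are measured on the same genes; it is a test of
  equal proportions, not of joint structure.
- Plug-in MI is biased upward at small N; no bias correction is applied
  because all inferences use the bootstrap null, which carries the same
  bias.
- Semantic-specificity magnitudes depend on the chosen edge weights;
  comparisons across ontologies or weight settings are not meaningful,
  and only within-analysis contrasts are reported.
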