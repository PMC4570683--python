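# Methods

## Normalization

Input is a gene × sample matrix of RPKM values over a factorial design
(default 4 cell lines × 4 treatments × 2 replicates = 32 samples), with a
per-gene origin flag (nuclear / mitochondrial). Mitochondrial genes are
normalized identically to nuclear genes and the flag is carried through
every step, so the matrix partitions losslessly at any stage.

- **Detection filter.** A gene is retained if RPKM > 0 in at least
  `min_samples` samples. The default requires detection in *all* samples —
  the strictest reading of "present in multiple experiments" — and the
  threshold is exposed because real datasets may warrant a looser rule.
- **Log transform.** `log2(RPKM + pseudocount)`. The log base is a
  convention, not a result-changing choice (Pearson correlation is
  invariant to it); base 2 is the transcriptomics default. The pseudocount
  defaults to 1.0 so exact zeros (possible under the simulator's dropout
  option and in real data) stay finite; 0 is allowed when all values are
  positive.
- **Median centering.** Each gene's log profile is divided by its own
  median, making the per-gene median exactly 1.0. The multiplicative
  (divide-by-median) reading was chosen over subtract-and-shift because the
  centered values are displayed and interpreted as fold-like ratios around
  1.0; the operation is idempotent, so re-centering is a no-op. Genes whose
  log-median is ≤ 0 cannot be centered this way without flipping the
  profile's sign; they are dropped with a warning rather than silently
  inverted. (With the default pseudocount of 1, log2 values are
  non-negative and a zero median means the gene is undetected in half its
  samples — such genes rarely survive the detection filter.)

## Co-expression score

For bait set S and gene g, `c(g, S)` is the arithmetic mean of the
non-negative standard (centered) Pearson correlations between g's
normalized profile and each bait member's. Rationale for discarding
negatives: bait sets like the extended complex I set contain sub-groups
under different transcriptional programs; a gene tracking one sub-group
should not be penalized for anti-correlating with another. Conventions the
definition leaves open, fixed here and exposed as flags:

- **Self-pairs.** When a bait gene is scored, its self-correlation (ρ = 1
  identically) is excluded by default; `include_self=True` restores it.
- **Empty positive set.** A gene with no non-negative bait correlation
  scores 0 (not NaN), keeping every gene rankable.
- **Scoring universe.** Nuclear genes only by default; mitochondrial genes
  stay in the matrix (they may be baits or correlates) but are not ranked.
- **Selection.** The top fraction (default 5 %) is exactly
  `floor(fraction × N)` genes — at N = 13,684 that is 684 — under a stable
  sort by descending score with ties broken by ascending gene id. The
  reported cutoff is the minimum selected score.

Score properties enforced by tests: c ∈ [0, 1]; invariance under positive
affine transforms of any single profile; exact agreement with a scalar
double-loop oracle.

## Clustering

Similarity for clustering is the *uncentered* Pearson correlation (cosine
similarity, no mean subtraction): on median-centered profiles the vector
mean carries signal (deviation from 1.0), so it is deliberately not removed
— this is a different statistic from the centered Pearson used in c(g, S),
and both are implemented separately. Distance is d = 1 − similarity
(range [0, 2]); anti-correlated profiles are maximally dissimilar, matching
the treatment of negative correlations in the score. Agglomeration is
average (UPGMA) linkage, implemented in-package with Lance–Williams updates
so the merge rule is fully specified: merge the minimal-distance pair, ties
broken by the lexicographically smallest pair of cluster ids (leaves
0..n−1 in input order, then creation order). Average linkage is reducible,
so merge heights are non-decreasing; tests cross-check the tree against
scipy's independent implementation via cophenetic distances. Tree cuts by
cluster count or by height; cut parameters are explicit because no single
cut rule is canonical. Sub-cluster enrichment is a one-sided (greater)
Fisher's exact test — the question is over-representation — with the
two-sided option available.

## TFBS enrichment

- **Promoters:** one window per annotated TSS, `[tss − h, tss + h)` with
  h = 2,000 bp by default (a 4 kb window). The window is symmetric, so
  strand only determines which coordinate of the input feature is the TSS
  (start on +, end − 1 on −). Windows truncated at a contig start are
  flagged. Multiple TSSs per gene give multiple, possibly overlapping
  windows, all retained.
- **Target map:** motif instances collapse to their TF; one overlapping
  site of any motif anywhere in any window makes the gene a target. Genes
  with promoter annotation but no sites are present with an empty TF set;
  genes without promoter annotation are absent.
- **Counting universe:** by default, enrichment counts only genes with
  promoter annotation (the background and test set are intersected with
  the annotated universe), which keeps all four cells of the contingency
  table well defined; `annotated_only=False` instead counts unannotated
  genes as universal non-targets.
- **Test:** one-sided (greater) Fisher's exact per TF, fold enrichment
  `(a/(a+b)) / ((a+c)/N)`, Bonferroni and Benjamini–Hochberg corrections
  over all tested TFs (delegated to statsmodels), and a report ranked by
  raw p with separate "individually significant" and "BH-significant"
  flags.

## Group-comparison tests

Mann–Whitney U (two groups), Kruskal–Wallis (several groups), one-way
ANOVA and the paired t-test, all thin, convention-fixing wrappers over
scipy with explicit sidedness and defined degenerate behavior (all-tied
data → p = 1; zero within-group variance with unequal means → p = 0 for
ANOVA, an error for the paired t). The Mann–Whitney p is computed by exact
enumeration when the combined sample size is ≤ 12 and the data are
tie-free (small fixtures deserve exact answers); with ties or larger
samples the tie-corrected normal approximation is used. Type-I error of
all four tests is verified to lie in [0.03, 0.07] at α = 0.05 under null
simulations. Per-sample mitochondrial expression is aggregated by sum
(default) or mean before testing, since the choice is not forced by the
analysis.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
the study-design scale:

- **Design:** full factorial, default 4 × 4 × 2 = 32 samples; the first
  half of cell lines are labeled control, the rest patient. The labeling is
  positional because the pipeline uses genotype only for grouping.
- **Expression:** log-expression(g, s) = baseline(g) + loading·factor(m, s)
  + ε with ε ~ N(0, noise_sd²), factor drawn i.i.d. N(0, 1) per sample, and
  RPKM = exp(log-expression) — any positive monotone link works since the
  analysis correlates log-scale profiles; exp keeps values strictly
  positive and log-normal-ish. Defaults: baseline log-mean 1.5 and log-sd
  1.5 (natural log; median ≈ 4.5 RPKM with a realistically heavy right
  tail), noise_sd 1.0, module loading 1.0 — giving an expected
  within-module Pearson correlation of loading²/(loading² + noise_sd²) =
  0.5, a strong but not degenerate co-expression signal. An optional
  per-treatment shift on a module's factor mimics treatment-driven
  responses; it is off by default because the co-expression math needs only
  shared variance.
- **TFBS:** each gene gets one TSS on a synthetic contig, spaced (10 kb)
  so promoter windows of different genes never overlap; target status is
  Bernoulli(p1 = 0.5) for the planted TF on its enriched gene set and
  Bernoulli(p0 = 0.1) otherwise; every target relationship is realized as
  1–2 motif intervals (8–14 bp) uniformly placed inside the promoter
  window. A fast path returns the target table without interval
  realization for large null calibrations.
- Ground truth (module membership, factor values, target table) is emitted
  with every dataset; recovery tests consume only the observable files.
  Same seed → bit-identical output.

**What passing tests do and do not show.** The simulator produces i.i.d.
log-normal noise, a single shared factor per module, one TSS per gene and
independent Bernoulli TF targets. Real RNA-seq has mean–variance coupling,
batch structure, correlated TF target sets (shared motifs between TF
families), multi-TSS genes and promoter windows that overlap between
neighboring genes. Recovery results here demonstrate correctness of the
machinery under the stated model, not expected sensitivity on real data.

## Problem sizes and numerics

The recovery suites run at 2,000 genes × 32 samples (10 seeds for module
recovery, 20 for TF recovery, 200 null runs, 2,000 calibration
replicates) — large enough for stable rates, small enough that the whole
suite runs in seconds. Oracle-equivalence checks use exact tolerances
(1e-12 for the score, 1e-9 on merge heights). Correlations are clipped to
[−1, 1] against floating-point overshoot; constant profiles yield
undefined correlations, which are excluded from scores with a warning
rather than propagated as NaN.

## Known limitations

- The multiplicative median-centering and the floor-based selection count
  are conventions; alternative readings (subtractive centering, ceiling at
  the boundary) are not implemented.
- No library-size or quantile normalization, no batch correction: the
  pipeline assumes RPKM input already comparable across samples.
- Per-TF target counts on a real conserved-TFBS resource depend on that
  resource's motif catalog and cannot be reproduced from simulation.
- The clusterer materializes the full distance matrix (O(n²) memory);
  fine for tens of thousands of genes, not for single-cell-scale inputs.
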