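# mitocoex

Bait-set co-expression scoring and conserved-TFBS promoter enrichment for
OXPHOS transcriptomics.

## The problem

Nuclear genes encoding subunits of the mitochondrial OXPHOS complexes are
transcribed as a coordinated program. Given a bulk RNA-seq experiment over
a factorial design (cell lines × treatments × replicates), one can exploit
that coordination to find *new* genes that follow the program of a known
complex — here, complex I (NADH:ubiquinone oxidoreductase) — and then ask
which transcription factors plausibly drive it, using conserved binding
sites in promoter regions. `mitocoex` implements that analysis as a tested,
reusable library for anyone working with an RPKM matrix, a bait gene set
and a conserved-TFBS annotation.

## The method

1. **Normalization.** Genes detected (RPKM > 0) in enough samples are
   log2-transformed and each gene's profile is divided by its own median,
   so the per-gene median is exactly 1.0 and values are fold-like
   deviations from the gene's typical level.
2. **Co-expression score.** For a bait set *S* (e.g. the nuclear complex I
   subunits plus the assembly factors NDUFAF1–4, TMEM126B, ACAD9), each
   gene *g* receives

   c(g, S) = avg { ρ(e[g], e[g′]) : g′ ∈ S, ρ(e[g], e[g′]) ≥ 0 },

   the mean of the *non-negative* Pearson correlations with the bait
   members. Negative correlations are discarded rather than averaged in,
   which keeps the score sensitive to genes tracking any positively
   co-regulated subset of the baits. Candidates are the top 5 % of the
   ranking over nuclear genes (at the 13,684-gene scale that is exactly
   684 genes).
3. **Clustering.** Expression profiles are agglomerated with average
   (UPGMA) linkage on d = 1 − uncentered Pearson (cosine) similarity; any
   sub-cluster can be tested for annotation enrichment with a one-sided
   Fisher's exact test.
4. **TFBS enrichment.** Promoters are 4 kb windows centered on every
   annotated TSS (2 kb up- and downstream). A gene is a target of a TF if
   any conserved site of any of the TF's motifs overlaps any of its
   promoter windows (≥ 1 bp, 0-based half-open). Per-TF over-representation
   of a candidate set against a background is a one-sided Fisher's exact
   test, corrected across TFs by Bonferroni and Benjamini–Hochberg.

A synthetic-data generator produces RPKM matrices with planted latent-factor
co-expression modules and TFBS annotations with a planted enriched TF, so
every stage is testable end to end without external data.

## Worked example

```sh
mitocoex simulate --seed 3 --outdir demo
mitocoex normalize demo/expression.tsv --origin demo/gene_origin.tsv --out demo/centered.tsv
mitocoex coexpress demo/centered.tsv --genesets demo/genesets.gmt --bait bait \
    --origin demo/gene_origin.tsv --out demo/coexp.tsv --selected-gmt demo/top.gmt
mitocoex enrich --tss demo/tss.bed --tfbs demo/tfbs.bed --motif-map demo/motif_map.tsv \
    --test-set demo/top.gmt --out demo/enrich.tsv
```

prints

```
wrote synthetic dataset (32 samples, 2000 genes) to demo
normalized 2000 genes × 32 samples → demo/centered.tsv
selected 100 genes (cutoff score 0.2407) → demo/coexp.tsv
50 TFs tested, 1 BH-significant at α=0.05 → demo/enrich.tsv
```

The dataset plants a 60-gene co-expression module and a TF that targets
those genes at probability 0.5 vs 0.1 background. The top-5 % selection
(100 of 2,000 genes; cutoff score 0.24 — the smallest selected c(g,S))
recovers the module, and the enrichment table ranks the planted TF first
(42 of the 100 candidates are its targets vs ~11 % of the background, a
3.3-fold enrichment, Benjamini–Hochberg p ≈ 2 × 10⁻¹²). The `examples/`
directory walks through the same stages from Python, one script per
capability.

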