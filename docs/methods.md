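# Methods

## Scope and data model

The package operates downstream of read quantification: its inputs are
gene × sample matrices of non-negative abundances (expected counts, FPKM
or similar), a sample table (tissue, species, replicate, optional batch),
a one-to-one ortholog table, a GO ontology (OBO 1.2) with gene→term
annotations, and qPCR Ct tables.  Alignment/quantification, batch-effect
removal, orthology inference, negative-binomial DE modelling and module
*discovery* are out of scope by design; where the pipeline needs such a
step to run end to end (the two-group DE test), a plainly labelled
stand-in is provided.

## Normalization

Raw abundances are transformed as log₂(N+1) and then quantile-normalized
across samples.  Base 2 keeps the transformed scale commensurate with the
|log₂FC| ≥ 1 DEG threshold.  Quantile normalization maps each value to the
across-sample mean of the column-sorted values at its within-column rank;
tied values receive the mean of their tied ranks' rank-means (interpolation
at the average rank), which makes the operation idempotent to numerical
tolerance.  An optional `batch` metadata column is carried and logged but
never used in computation.

## Tissue specificity (τ)

τ = Σᵢ(1 − x̂ᵢ)/(n − 1) with x̂ᵢ = Xᵢ/maxᵢXᵢ is computed per gene over
per-tissue **means** of the normalized log-scale data.  Mean (not median)
summarization follows the established τ literature; the order of
operations is normalize → summarize → τ.  Choices for cases the index
definition leaves open:

* all-zero genes: τ undefined; the gene is excluded from calling and
  counted.
* ties in the maximal tissue mean: τ is computed normally but the gene is
  never called specific — a tie contradicts tissue-specificity.
* replicate consistency: the calling rule "the samples with the highest
  expression come from the top tissue" is made precise as: the top r
  samples by expression (r = replicate count of the top tissue) must all
  carry the top tissue's label.
* calling threshold: τ > 0.9, strict; each gene is assigned to at most one
  tissue.  Cross-species "common" genes are ortholog pairs called in the
  same tissue of both species.

τ is invariant under positive rescaling of a gene's expression vector and
monotone in the dominant tissue's expression; both are enforced by
property tests, and the production implementation is checked against a
naive loop transcription of the definition to 1e−12 on 1000 random
profiles.

## GO semantic similarity

Term similarity is Wang's graph measure: within a term's ancestor
closure, S-values propagate from the term (S = 1) through child→parent
edges, each step multiplied by the relation weight — w(is_a) = 0.8,
w(part_of) = 0.6, the GoSemSim-style defaults.  The similarity of two
terms is the sum of both terms' S-values over their shared ancestors,
divided by the sum of their total semantic values.  Set similarity is the
best-match average (BMA): each term's best match in the opposite set,
averaged over both directions.  Cross-namespace sets are scored per
namespace and combined by a term-count-weighted average; terms whose
namespace is absent from the other set are dropped with a warning, and a
set left empty by filtering is an error (distinct from similarity 0).

Significance: the observed BMA between two term sets is compared with
`n_perm` = 1000 BMAs of equally sized term sets drawn independently
without replacement from the reference universe — all terms annotated to
at least one gene in the reference annotation map, not the whole
ontology.  The observed value is "significant" at or above the null's
95th percentile (the one-sided rule as stated); the result also reports
the observed value's percentile rank so a *low* similarity (functional
distinctness) can be read off directly, and the empirical p-value uses
the +1 (Phipson–Smyth) correction so it is never 0.  Under the null the
rejection rate is calibrated to ~5% (checked over 200 seeded
repetitions, accepted within [0.01, 0.12], the exact binomial band).

Enrichment (`enrich_terms`) is a one-sided hypergeometric upper tail per
term with ≥ 1 study annotation, with true-path propagation of annotations
to ancestors by default, and Benjamini–Hochberg adjustment across tested
terms.

## Differential expression and 2^−ΔΔCt

The two-group test is Welch's t on log-scale values per gene with
log₂FC = mean(A) − mean(B); it is runnable plumbing, not a reimplementation
of shrinkage-based DE models.  Genes with zero variance in both groups get
p = 1 (equal means) or p = 0 (unequal) by convention.  DEGs are called at
raw P < 0.05 **and** |log₂FC| ≥ 1 (fold change ≥ 2); the boundary is
included for the fold change and excluded for p.  No multiple-testing
adjustment enters the call — matching the stated thresholds — but the BH
p-value is computed and reported alongside to expose the gap.  The
gill-vs-four-tissues intersection requires direction consistency by
default (up everywhere, or down everywhere); a `membership` mode is
provided because the original rule's strictness is ambiguous.  Relative
qPCR expression is 2^−ΔΔCt with ΔCt = Ct_target − Ct_reference per sample
and ΔΔCt against the mean ΔCt of the control condition; the method is
invariant to a constant Ct offset.

## Co-expression modules

Module assignments are an input (upstream network analysis or the
generator's truth) — the soft-threshold/tree-cut discovery machinery is
deliberately not reimplemented.  On top of an assignment:

* eigengene: first principal component (SVD) of the module's gene-wise
  standardized submatrix, unit-norm over samples, sign-oriented so the
  mean member correlation is ≥ 0;
* merging: average-linkage clustering of eigengenes at dissimilarity
  1 − r, cut at height 0.2; merged modules keep the largest constituent's
  label; eigengenes are recomputed and the procedure iterates until the
  module count is stable (termination is guaranteed because the count
  strictly decreases);
* module–trait: Pearson r against per-sample numeric traits (tissue
  one-hot indicators by default, species optionally) with two-sided
  Student-t p;
* MM/GS: per-gene Pearson correlation with the own-module eigengene and
  with the target trait indicator; zero-variance genes are flagged
  undefined; hub genes satisfy MM > 0.8 and |GS| > 0.2;
* network export: unsigned TOM with adjacency |cor|^β, β = 6 (configurable),
  TOMᵢⱼ = (Σᵤ aᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ); edges at weight ≥ 0.3.
  TOM (rather than raw adjacency) is used for the exported weight; a flag
  switches to adjacency if desired.

## Synthetic data

The generator emulates the structure of a two-species (terrestrial vs
coastal), five-tissue (antennae, compound eyes, gills, nerve, pereopods),
~3-replicate design over ~10,000 ortholog-paired genes; the 29-sample
layout is realized by giving one tissue of species B one replicate fewer.
On the log₂ scale:

* background genes: level μ_g ~ U(1, 6) plus N(0, noise_sd = 0.5)
  per-sample noise;
* planted tissue-specific genes (`specific_fraction` = 0.05, split evenly
  over tissues): OFF outside their tissue — a half-normal leak
  |N(0, 0.1)| around zero, the log-scale signature of an unexpressed
  gene — and expressed at `effect_log2` (default 3) plus a U(0, 5)
  gene-level offset inside it.  An elevation-over-an-ordinary-baseline
  model cannot produce τ > 0.9 at any plausible effect size (τ ≤
  1 − μ/(μ+effect) ≤ 0.75 for μ ≥ 1, effect = 3), so the off-state model
  is the only construction under which τ-calling is a meaningful target;
  with `effect_log2` = 0 the planted genes collapse into flat leak noise
  and the false-call rate stays below 1%;
* planted gill-DE genes (`de_fraction` = 0.02, half up, half down):
  background baseline plus a signed `effect_log2` shift in gill samples
  only; down-shifted genes draw their baseline from U(1+effect, 6+effect/2)
  so the depressed level stays positive rather than being clipped below
  the detectable range;
* planted modules (5 × 120 genes): a shared per-tissue latent factor,
  standardized over the sample design, added with amplitude 1.5; the
  first module's factor is the gill indicator, making it the
  trait-coupled module; module genes draw μ_g ~ U(3, 6) to avoid clipping;
* two species: one blueprint, independently re-rendered noise, plus a
  per-gene-per-tissue divergence shift N(0, 0.25); a `discordant_fraction`
  of gill-specific genes lose specificity in alternating species; a
  `species_de_fraction` of background genes get a gill-only
  between-species shift (half per direction);
* ontology: one root, five disjoint cluster sub-DAGs each seeded by a
  parent chain of the requested depth; non-root terms take 1–2 in-cluster
  parents (is_a 80% / part_of 20%).  Genes draw 2–10 terms from their home
  cluster with probability `coherence` (planted tissue sets are pinned to
  dedicated clusters), otherwise from the whole pool.

Raw values are emitted as 2^v − 1 so that log₂(N+1) recovers the log scale
exactly; a Poisson mode (counts ~ Poisson(2^v − 1)) exists for realism
checks.  Everything is a pure function of (parameters, seed).

What the generator does **not** emulate: read-level sampling noise,
library-size and GC composition effects, batch structure, dispersion
heterogeneity, correlated ortholog divergence, or the real GO's scale and
shape.  Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated generative assumptions, not
end-to-end performance on real sequencing data.

## Problem sizes and numerical choices

Recovery checks run at the full design scale (10,000 genes × 29 samples),
which completes in seconds; permutation calibration uses 200 repetitions
of 200 permutations each, and the end-to-end determinism check runs the
pipeline twice at 1,000 genes with 200 permutations.  Wang S-values and
pairwise similarities are memoized per ontology so permutation BMAs cost
dictionary lookups.  Oracle comparisons are asserted at 1e−12; quantile
normalization idempotence at 1e−9.  Pearson correlations are clipped to
[−1, 1] before the t transform, and |r| = 1 maps to p = 0 explicitly.

## Known limitations

* The two-group DE stand-in has low power at 2–3 replicates and no
  dispersion sharing; at the default planted effect of 3 log₂ units the
  four-way intersection recovers ≥ 90% of planted DEGs, but weaker
  effects (≤ 2) fall below that with n = 3.
* The permutation test draws the two term sets independently, so their
  overlap distribution differs slightly from schemes that draw disjoint
  sets; the calibration test bounds the practical consequence.
* Module merging recomputes full eigengenes each round; for very many
  modules a profile-sketch approach would be faster.
* `enrich_terms` tests every annotated term independently; parent/child
  dependence is not modelled (as is standard for plain hypergeometric GO
  enrichment).
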