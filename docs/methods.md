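# Methods

`hemnet` implements a pan-disease transcriptomic analysis for cohorts that
span many related malignancies: it asks which genes, transcription factors
(TFs) and TF–gene regulations are *specific* to one disease, which are
*shared* by groups of diseases, and what those patterns imply at the level
of biological pathways. All stages are exercised on synthetic cohorts with
planted ground truth, so every statistical claim the package makes is
backed by a recovery or calibration test.

## Disease-specificity score

For feature *j* (a gene, a TF, or a regulation) and disease *d*, with
expression (or edge weight) observations *e_j* pooled over all subjects
(or all disease networks),

    s_j^d = ( median(e_j^d) − median(e_j) ) / IQR(e_j)

i.e. the deviation of the disease median from the pooled median in units
of the feature's pooled interquartile range. The score is location- and
scale-invariant, so no per-feature normalization is needed. Conventions:

- Q1/Q3 use linear interpolation between order statistics (numpy's
  default quantile rule), fixed for reproducibility.
- The pooled IQR includes the disease under test; a zero IQR marks the
  feature as undefined and removes it from null fitting and calls.
- For regulations, each disease network contributes exactly one
  observation per edge, so the disease "median" is that single weight.

Because the overwhelming majority of features are not disease-specific,
the pooled score distribution is approximately Gaussian around zero. The
null is moment-fitted (mean, sample SD) separately per feature class
(genes, TFs, edges), since the classes have visibly different scales; on
the default synthetic cohort the gene-score null has σ ≈ 0.29 and the
edge-score null σ ≈ 0.92 (both printed by the drivers; both are
cohort-dependent quantities, not constants). P-values are one-sided upper
tail — over-expression is the direction of interest — then
Benjamini–Hochberg adjusted within the feature class. A feature is called
specific in a disease when

    score > 2   and   adjusted p < 0.01.

The adjusted-p reading is the default; `use_adjusted_p: false` switches
the call to raw p-values. A feature's **multiplicity** is the number of
diseases in which it is called specific.

## Disease clustering

Diseases are embedded as score vectors over all defined features and
compared by Euclidean distance. The dendrogram uses complete linkage
(inter-cluster distance = maximum member pair), whose merge heights are
non-decreasing. The cut is an adaptive branch-pruning rule in the spirit
of dynamic tree cut: walking top-down, a branch is split when its merge
height exceeds the mean of its descendant merge heights by more than
`prune_gap_fraction` × (global height range); defaults
`prune_gap_fraction = 0.25`, `min_cluster_size = 2`. Two-leaf branches are
never split below themselves; leaves peeled off at a split are reported as
singleton clusters. The strict inequality means a tree whose merges all
occur at one height is a single cluster. Both constants are exposed in the
configuration because no canonical values exist for the desk-scale data.

## PANDA-style network inference

Per disease, a gene–gene Pearson co-expression matrix is computed over
that disease's subjects (≥ 3 required; zero-variance genes get zero
correlations). Message passing then integrates three evidence sources —
the TF×gene motif prior W₀, the TF×TF cooperativity prior P, and the
gene×gene co-expression C — all first normalized as
X' = (Zrow + Zcol)/√2 (two-pass z-score; zero-variance rows/columns fall
back to the overall matrix z-score; sample SD, ddof = 1).

Each iteration *t* computes a continuous Tanimoto similarity

    T(X, Y)_ij = (XY)_ij / sqrt( ||X_i·||² + ||Y·_j||² − |(XY)_ij| )

to form responsibility R = T(P, W) and availability A = T(W, C), then

    W ← (1−α)·W + α·(R + A)/2
    P ← (1−α)·P + α·T(W, Wᵀ)      C ← (1−α)·C + α·T(Wᵀ, W)

with each of P, C followed by a diagonal refresh: diagonal entries are
replaced by (off-diagonal row SD) × dimension × exp(2αt), which keeps
self-similarity from dominating the messages. Iteration stops when the
mean absolute change of W falls below `tolerance` (default 10⁻³, α = 0.1,
at most 200 iterations; non-convergence is recorded in the result, which
is still returned). At α → 0 the network is exactly the normalized motif
prior; the implementation is checked to 10⁻⁸ against an independent
loop-based transcription of the updates. All 13 default-scale networks
share the same priors and differ only through co-expression, so
between-disease differences in edge weight are co-expression-driven by
construction.

A practical note on the availability channel: an edge TF→g is lifted when
g's co-expression partners coincide with the TF's other targets. A prior
that covers a co-expressed block therefore reinforces the whole block,
while block genes *outside* the prior row count against it — toy recovery
tests must plant priors that cover their blocks.

## GSEA batteries

Preranked GSEA with the weighted Kolmogorov–Smirnov statistic: walking a
descending ranking, hits add |stat|^p / Σ_hits |stat|^p (p = 1 by
default), misses subtract 1/(N − N_hits); the ES is the signed maximum
deviation and the **leading edge** ("driving genes") are the set members
on the extremum side. Rank ties are broken by gene id so rankings are
reproducible.

Significance uses a random-gene-set permutation null with the plus-one
estimator on the **absolute** ES:

    p = (1 + #{ |ES*| ≥ |ES| }) / (1 + n_perm)

This is the Monte-Carlo rank of |ES| among exchangeable draws, hence
exactly uniform under the null whatever the asymmetry of the ES
distribution — the signed-one-sided alternative is uniform only within
each sign and would double the nominal false-positive rate. The ES sign
still records direction and chooses the leading-edge side. Permuted ES
values are computed from hit positions alone (running-sum extrema occur
at hits or just before them), vectorized over permutations; tests verify
exact agreement with the full walk.

Two batteries mirror the study design:

- **expression**: per (disease, pathway), ranking by the disease's median
  expression; joint BH; adjusted p < 0.01. Full-scale analogue
  186 × 13 = 2418 tests.
- **regulation**: per (disease, TF, pathway), ranking by the TF's weight
  row; joint BH; adjusted p < 0.05. Full-scale analogue
  186 × 13 × 609 ≈ 1.47 M tests.

Permutation resolution matters with BH: the smallest attainable adjusted
p is roughly (1/(n_perm+1)) · m / k for m tests and k true signals, so a
battery of ~300 tests thresholded at 0.01 needs n_perm ≈ 2×10⁴, while the
0.05 threshold is reachable at the 500-permutation default only when the
battery is small. The operation defaults are 2000 (expression) and 500
(regulation); the pipeline drivers raise them to 20000 / 4000 so the
thresholds are attainable at their battery sizes. This bound is fixed by
arithmetic, not by data.

## Intersection-based signatures

Three groupings, all keyed by *exact* disease sets:

1. **Shared over-expressed genes** — genes with identical specificity-flag
   patterns define a group; multiplicity-1 genes are each disease's own
   specific list.
2. **Shared pathways** — each significantly enriched pathway nominates the
   set of diseases where it is significant; pathways are annotated with
   the number of driving genes common to all members (intersection of
   leading edges). A zero count is kept but flagged — it marks enrichment
   carried by disjoint genes.
3. **TF–pathway clusters** — a (pathway, TF) pair significant in several
   diseases forms a cluster only when the intersection of the leading
   edges is non-empty (same pathway + same TF + at least one common
   driving gene). This strict rule deliberately narrows the output to the
   most interpretable clusters.

A user-supplied annotation table (id → disease associations / drug flags)
can decorate any group; annotations live alongside the items, so stripping
them restores the original groups.

## Synthetic cohorts

The generator emulates the statistical shape the analysis assumes, at a
desk scale of 13 diseases × 40 subjects and 500 genes of which the first
50 are the designated TFs:

- per-gene baselines m_g ~ N(7, 2²) log2 units and dispersions
  σ_g ~ U(0.3, 1.2), matching the magnitude and spread of summarized
  microarray intensities;
- optional latent factors in gene blocks (default 10 factors, loading
  scale 0.5) for realistic co-expression structure;
- planted over-expression: (gene, disease, δ) shifts of
  δ × (realized pooled IQR of that gene before shifting), so the score
  threshold of 2 maps directly onto δ — a δ = 3 plant lands near score
  2.6 because the shift itself inflates the pooled IQR by ~10–15%;
- planted regulations: (TF, gene, disease, strength) couple the target to
  its TF's standardized profile within one disease, elevating their
  within-disease correlation, and force the edge into the motif prior;
- Bernoulli motif (density 0.05) and symmetric TF–TF (0.1) priors.

What the generator does **not** emulate: batch effects and their
correction, probe-level artifacts, heavy-tailed or bimodal expression,
disease-specific co-expression rewiring beyond planted couplings, and
unequal real-world group sizes. Passing recovery tests therefore show the
statistics behave as designed under their own assumptions, not that the
pipeline is robust to real microarray pathologies.

Because the motif prior is shared across diseases, a planted regulation
block is enriched in *every* disease's network (the common shape of
TF–pathway clusters in this kind of analysis); disease-discriminating
enrichment arises in the expression battery, where planted pathway shifts
are confined to their diseases.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `score_threshold` | 2 | specificity call, in pooled-IQR units |
| `p_gene` | 0.01 | adjusted-p threshold for gene/TF/edge calls |
| `p_pathway_expr` / `p_pathway_reg` | 0.01 / 0.05 | battery thresholds after joint BH |
| `alpha` | 0.1 | PANDA update rate |
| `tolerance` | 10⁻³ | PANDA stop on mean abs ΔW |
| `max_iterations` | 200 | PANDA iteration cap |
| `permutations_expr` / `permutations_reg` | 2000 / 500 | GSEA permutation defaults |
| `prune_gap_fraction` | 0.25 | dendrogram branch-cut gap, fraction of height range |
| `min_cluster_size` | 2 | smaller branches reported as singletons |

## Numerical choices and degenerate inputs

- All TSV floats are written at 17 significant digits and parsed with
  round-trip precision, so writer/reader pairs are bit-lossless.
- Undefined scores (zero IQR), zero-variance genes in correlation, flat
  rows in normalization and zero Tanimoto denominators are each handled
  by explicit, documented fallbacks rather than NaN propagation.
- Exact ties between the positive and negative ES extremum are broken
  toward the positive side; at floating-point precision a tie may resolve
  either way, which only ever affects the sign of an |ES|-symmetric case.
- All randomized stages derive their generators from explicit seeds;
  equal seeds give bit-identical outputs.

## Problem sizes used by the test suite and drivers

Recovery runs use the default 13 × 40 × 500-gene scale (20 seeds for the
averaged sensitivity/false-discovery check); null calibration uses
20 pathways × 13 diseases for the expression battery (fresh pathway draws
per disease, since near-identical median rankings would otherwise leave
only ~20 independent tests) and 20 × 13 × 50 for the regulation battery;
PANDA oracle checks run on 3 TF × 5 gene toys and recovery toys at
3 × 30. These sizes were chosen so the full pipeline remains a
minutes-scale desk computation.

## Known limitations

- The Gaussian null is a pragmatic approximation; with few subjects per
  disease the score null has heavier tails than Gaussian, which the
  calibration test bounds but does not remove.
- Plain Monte-Carlo permutations bound attainable p-values; very large
  batteries at strict thresholds need proportionally more permutations
  (no multilevel/analytic tail approximation is implemented).
- Dynamic-tree-cut parameters are heuristics; cluster memberships on
  weakly separated data are sensitive to `prune_gap_fraction`.
- Edge-specificity pools 13 observations per edge (one per disease), so
  its quartiles are coarse; scores are comparable across edges but their
  null is wider than for genes.
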