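# Methods

## Proximity graphs

Cell contacts within one ROI are modeled as the edges of the Delaunay
triangulation of the cell centroids, pruned to Euclidean length ≤ 50 μm
(inclusive; `max_edge_len` is a parameter). Coordinates are taken verbatim
in μm with no origin convention. Delaunay adjacency approximates "touching
or nearly touching" better than a pure radius graph in dense tissue because
it never links cells that have another cell between them; the 50 μm prune
removes the long convex-hull edges that triangulation introduces at the
tissue boundary.

Degenerate inputs are handled so downstream statistics stay defined: ROIs
with fewer than 3 cells, or with all cells collinear, fall back to the
complete graph pruned at the same cutoff; exact duplicate coordinates are
jittered by at most 1e-6 μm using a generator seeded from the ROI id (the
affected cell ids are recorded on the graph object), keeping runs
bit-reproducible while satisfying the triangulation's general-position
requirement.

## The geometric interaction odds ratio

For cell types A and B with `nA`, `nB` cells and observed within/across
contact counts `eAA`, `eBB`, `eAB`, the possible-contact totals are
`N_AB = nA·nB`, `N_AA = nA(nA−1)/2`, `N_BB = nB(nB−1)/2` and each odds is
observed contacts over remaining possible contacts. OR* divides the
across-type odds by the geometric mean of the within-type odds. Note the
denominators count *all* pairs, not only geometrically realizable edges;
this is deliberate — it is the statistic as defined — but it couples OR* to
ROI size: a planar graph has O(n) edges while N grows as O(n²), so OR* of a
well-mixed ROI approaches 1 only because the three odds shrink at the same
rate, and OR* values should be compared across ROIs of similar cell count.

**Degeneracy policy.** Whenever any observed count is 0, equals its
possible total, or any possible total is 0 (e.g. `nA = 1`), the
Haldane–Anscombe correction `odds = (e + 0.5)/(N − e + 0.5)` is applied to
all three odds and the result is flagged `corrected`. Correcting all three
(not just the offending one) preserves the A↔B symmetry of OR*. Raw odds
are reported alongside as 0/inf/nan.

**Permutation null.** The label vector is permuted uniformly over the
graph's nodes (all labels participate, including types other than A/B),
OR* is recomputed with the same correction policy, and the one-sided
empirical p uses the add-one convention
`p = (1 + #{OR*_perm ≥ OR*_obs}) / (1 + n_perm)`, which cannot be zero.
Randomness is a counter-based Philox stream keyed by
`(seed << 32) | crc32(roi_id)`, making ROIs independent under one seed and
runs reproducible. Pooling counts across an individual's ROIs before the
odds computation is available (`pool_edge_counts`); whether to score per
ROI or per individual is left to the caller.

## Ligand–receptor scores

`P = L·R / OR*` with the corrected OR* whenever correction was triggered
(P is undefined at OR* = 0). The per-ROI score is the geometric mean over
the panel pairs found in both matrices; missing genes skip their pair with
a recorded reason and reduce n. A zero L or R zeroes the whole score
(geometric-mean semantics); callers who need strictly positive scores can
add a floor ε to L and R (default 0). For cell-level matrices,
`aggregate_cells_to_roi` collapses cells of a named type to per-ROI means
first, since region transcriptomes are aggregates. Dividing co-expression
by OR* down-weights spatially well-mixed ROIs; whether that matches a
"recruitment" reading of the score is an interpretive question the package
does not resolve — the formula is implemented exactly as defined.

## Signature scores

`module_score` re-implements the binned-control scheme: genes are split
into `n_bins` (default 24) equal-size bins by average expression across
units; each signature gene draws `n_ctrl` (default 100) control genes with
replacement from its bin; the unit's score is mean(signature) − mean(pooled
controls). The scheme is additive-shift invariant and centers at zero for
uninformative signatures. Bin count, control count, and seed are recorded
in the result's params. Note a pitfall on small matrices: if a bin contains
only signature genes, controls cancel the signal — use coarser bins.

`ssgsea_score` is the rank-weighted running-sum statistic: per unit, genes
get ascending ranks (highest expression = rank N, ties averaged); walking
the gene list in descending expression order, the score accumulates the gap
between the in-set cumulative fraction of `rank^alpha` weights (alpha
default 0.25) and the uniform out-of-set cumulative fraction. It depends
only on each unit's ranking, hence is invariant to per-unit monotone
transforms. Scores are not rescaled across units; compare within a run.

`rank_de_test` runs two-sided Wilcoxon rank-sum per gene after the standard
single-cell pre-filters (|Δ mean log expression| > 0.25 and percent
expressed > 25% in at least one group, both configurable), with Bonferroni
(marker use) or Benjamini–Hochberg correction over tested genes only. The
log fold change is the difference of group means of log-normalized values
(natural log). The same Wilcoxon engine backs the continuum's per-sample
DE; a hurdle-model DE engine could be substituted upstream without changing
the continuum machinery, which consumes generic (gene, log_fc, p) tables.

Spearman correlations use tie-corrected ranks, the t approximation for
n ≥ 10 and the exact permutation distribution below that; constant inputs
are defined as rho = 0, p = 1.

## Normalization

`normalize_log_cpm` computes `ln(1 + count/total × 1e6)` per unit. The +1
pseudocount is recorded in the result's state; zeros map to zero and the
transform is monotone and compositionally invariant within units.
Region-level inputs normalized by other pipelines (e.g. upper-quartile
scaling) enter as `norm_state="arbitrary"`; whether to log them before
signature scoring is the caller's choice.

## The basal transition continuum

Gene selection: samples must have **more than** 50 basal cells (strict);
each surviving sample's DE table is BH-adjusted and a gene is kept iff
`p_adj ≤ 0.05` and `|log2FC| ≥ 0.5` in at least 2 samples. Pseudobulk is
the per-sample mean of log-normalized basal-cell expression over the
selected genes — PCA is across samples, not cells, because the continuum
is interpreted per sample against per-sample immune fractions. Genes are
z-scored over samples (zero-variance genes dropped with a warning), the
first two principal components are taken from the SVD with a deterministic
sign convention, and a loess curve (tricube weights, local degree 2, span
default 0.75) of PC2 on PC1 is evaluated on a 200-point grid to form the
spline polyline. The loess smoother is implemented in-package as a
~40-line weighted local polynomial fit, since the degree-2/tricube/span
combination is not exposed by the installed statistics libraries.

The scalar coordinate is cumulative arc length along the polyline at the
vertex nearest the sample's PC-plane position (ties to the lower arc
length); the residual distance to that vertex is reported as a fit
diagnostic. Orientation is fixed by requiring the lexicographically
smallest training sample id to fall in the lower half of the coordinate;
with cohort naming conventions that start at the reference/control sample
this anchors "low coordinate = reference-like", and it removes the
reflection ambiguity of PCA. External profiles (e.g. spatial EPI ROI
transcriptomes) are standardized with the *training* means/sds, projected
onto the training loadings, and snapped to the same polyline; they must
cover ≥ 50% of the model genes, with absent genes imputed at the training
mean (z = 0). Placement of a training sample through the model reproduces
its training coordinate to within one grid step by construction.

`fraction_trend` reports, per immune population, Spearman rho and p of
fraction versus normalized coordinate plus a 50-point loess curve.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

- **Spatial ROIs** (default 100+100 cells, 1000 μm field, cluster sd
  50 μm): mixing λ contaminates per-cell cluster placement with uniform
  placement at probability λ. Cluster centers sit `8·cluster_sd + 50` μm
  apart so that at λ=0 cells within 4 sd of their own center cannot form
  across-type contacts at the 50 μm cutoff; across-type contact frequency
  increases monotonically in λ. A Gibbs interaction model would give finer
  control of pairwise attraction but is unnecessary for validating a
  statistic that only needs an ordered family of mixing levels.
- **ROI expression**: ligand (EPI) and receptor (IMM) values are
  `base · exp(κ · eAB/N_AB + noise)`, log-normal noise sd 0.1, filler genes
  i.i.d. Because mixedness `eAB/N_AB` scales like 1/n (planar edges grow
  linearly, possible pairs quadratically), the coupling is only detectable
  in small dense ROIs; validation uses 6+6-cell ROIs in a 180 μm field.
- **Continuum cohorts** (default 20 samples × 200 cells × 100 genes):
  latent t evenly spaced on [0, 1]; 15 module-A genes gain
  `effect_size · t` (default 1.5) in log mean, 15 module-B genes lose it;
  counts are negative binomial with variance `μ + μ²/dispersion`
  (dispersion 10); a tracked immune population's fraction is
  `0.1 + 0.5·t + N(0, 0.02)` truncated to [0, 1].

What the generators do *not* emulate: probe-level measurement noise,
segmentation error, batch structure, compositional coupling between cell
types, or realistic gene–gene correlation. Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
signal under idealized noise — not performance on real spatial profiling
data.

## Problem sizes and numerical choices

Validation runs use the sizes stated above (200-cell graphs, 2000
permutations, 50 replicates per mixing level, 20-sample cohorts), chosen as
the smallest sizes at which the stochastic properties stabilize. Exact
arithmetic checks are held to 1e-12 relative; geometry-dependent
comparisons to 1e-9. Tie-breaks: average ranks in all rank statistics;
stable sort order for equal-expression bins; lower arc length for
equidistant spline vertices. Error handling favors loud failure — schema
violations, absent labels, empty gene selections, and insufficient overlap
all raise with the offending identifier in the message.

## Known limitations

- OR* depends on ROI cell count through its all-pairs denominators (see
  above); cross-ROI comparisons assume comparable n.
- The continuum's loess spline is fit on samples, so cohorts with n < ~8
  give noisy curvature; the spline degenerates gracefully to a straight
  segment when PC2 carries no structure.
- No multi-type (> 2) generalization of OR*, no k-NN or radius-ball
  alternative graphs, no 3-D coordinates, and no gene-symbol aliasing.
- Example signature GMTs are illustrative; real analyses must supply
  curated signatures.
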