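# Methods

## The study shape

The pipeline targets expression studies of a clonally replicated scion
grafted to several rootstocks and sampled repeatedly across seasons: two
tissues (leaf, reproductive), three years, three phenological stages
(anthesis, veraison, harvest-ripe), four rootstock treatments (own-rooted
plus three rootstocks), replicated blocks with an irrigation treatment
nested on blocks, and an on-site weather station recording ten hourly
variables. One design cell — reproductive tissue at the final year's
harvest — is empty, as happens in the field when fruit is lost; all stages
tolerate it, and the study validator reports it as an empty cell rather
than an error.

## Normalization and the VST

Counts are modeled as negative binomial with Var(K) = µ + α(µ)µ² and a
parametric dispersion trend α(µ) = a₁/µ + a₀ (a₁ captures Poisson-like
extra spread at low means, a₀ the asymptotic biological dispersion).

* **Filtering** retains gene *g* iff its size-factor-normalized count
  strictly exceeds `min_count` (default 4) in at least `min_samples`
  (default 4) samples. Filtering on raw counts is available
  (`scale="raw"`); normalized is the default.
* **Size factors** are median-of-ratios over the reference set of genes
  with no zero count, rescaled to geometric mean 1. For sparse matrices a
  pseudo-reference (geometric mean over positive counts) is available
  behind a flag.
* **The trend** is fitted by Huber robust regression of method-of-moments
  gene dispersions α̂ = max(0, (var−µ)/µ²) on 1/µ, using genes with mean
  above 1; negative coefficients clip to zero. The moments are *marginal*
  — computed across all samples without removing design effects — so
  planted or real biological signal inflates a₀ somewhat (on the default
  synthetic study the planted a₀ = 0.1 fits near 0.3). This biases only
  the curvature of the transform, not the downstream inferences, which use
  the VST as a monotone variance-flattening map; the clean-recovery test
  (no design effects) fits (0.1, 1) within a few percent.
* **The VST** integrates 1/√w with variance function w(q) = (1+a₁)q + a₀q²
  in closed form and is rescaled so vst(q) − log₂(q) → 0 for large q:
  vst(q) = log₂(2a₀q + b + 2√(a₀q(a₀q + b))) − log₂(4a₀), b = 1 + a₁.
  When a₀ is numerically zero there is no log asymptote and the Poisson
  square-root stabilization 2√(q/b)/ln 2 is used instead.
* Genes constant after the VST are flagged by `scale_genes` (all-zero rows)
  and dropped by the pipeline with a logged warning.

## Variance partitioning

Per gene, z-scored VST expression is decomposed by sequential (Type-I) sums
of squares in a fixed, documented order: tissue, year, phenology,
irrigation, rootstock, then the pairwise interactions of
{rootstock, tissue, year, phenology} in lexicographic pair order. The
sequential scheme was chosen because fractions then sum exactly to one with
the residual, making "variance explained by rootstock" unambiguous; with a
complete balanced design the main-effect fractions are order-invariant
(tested). Year and phenology are unordered factors. Columns aliased by
missing cells are dropped greedily in declared order and recorded once.
The decomposition is computed from an in-order QR basis and verified
against explicit nested projections to 1e-8 on random small designs.

Selection keeps genes whose rootstock fraction is **at or above** the
q = 0.75 linear-interpolation quantile (inclusive threshold, so ties at the
threshold are kept).

## Self-organizing map

The map is a 9 × 9 hexagonal lattice in offset-row layout with unit
nearest-neighbor spacing; neighborhoods use planar Euclidean distance.
Training is online: 500 epochs of full-data presentation in seeded random
order; for each input the best-matching unit (BMU) is the Euclidean-nearest
node (ties → lowest node index) and every node moves by
α·h(d)·(x − w) with Gaussian h = exp(−d²/2r²) (a bubble kernel is
available). The learning rate interpolates linearly 0.05 → 0.01 and the
radius from two-thirds of the grid diameter down to 0.5, both over the
total update count. Initialization samples distinct input rows (default)
or a lattice in the top-2 PC plane. These choices — kernel, radius
schedule, initialization, tie rules — are design decisions exposed as
configuration, since only the grid, epoch count, and learning-rate range
are fixed by the procedure being reimplemented.

Per node, genes with distance at or below the node median are retained
(inclusive; singletons survive). Nodes with ≥ 16 retained genes are tested
by a one-way rootstock F-test on the per-sample mean of retained genes,
significant at α/81 (Bonferroni by node count). Note that at the default
synthetic scale (500 selected genes over 81 nodes, ~3 retained genes per
node) essentially no node reaches the 16-gene floor — the floor is
calibrated to the original data's scale (~5,500 selected genes), so the
scaled-down study honestly reports zero tested clusters while the
dedicated power simulations exercise the test itself.

## Environmental composite statistics and G×E screening

Each averaged weather feature contributes min, max, change, and mean over a
24 h window; precipitation and radiation density contribute sums, giving
8 × 4 + 2 = 34 columns by default (the feature list and per-feature stat
set are configuration). "Change" is defined as max − min within the window
(a last-minus-first definition would be sign-sensitive to the anchor and is
not used). Windows are the half-open interval (anchor − 24 h, anchor];
the all-days table anchors each calendar day at the following midnight, so
sampling-day rows extracted from it summarize the sampling day itself.
Windows missing more than 25% of expected hours raise an error
(configurable).

The environmental PCA standardizes the all-days composite table and
decomposes it by SVD; the expression PCA centers the VST matrix
(samples × genes) without unit-scaling, since VST values share a scale.
Both use a deterministic sign convention (largest-|loading| positive).
Components are selected as the smallest prefix reaching 80% cumulative
variance. Samples inherit their sampling day's ePC scores.

Each (gPC, ePC) pair is fit by OLS with terms in fixed sequential order:
environment, tissue, rootstock, env:tissue, env:rootstock,
tissue:rootstock, env:tissue:rootstock — the same Type-I convention as the
variance partition. Terms explaining strictly more than 5% of the gPC's
variance are flagged. For flagged rootstock-by-environment terms, the
per-rootstock slope of the gPC on the ePC is the model derivative averaged
over tissue levels with equal weight; pairwise slope differences are
referred to the studentized-range distribution with k = number of
rootstocks on the residual df (classic Tukey adjustment; for k = 2 this is
exactly the two-sided t-test, verified to 1e-10). Genes loading beyond
mean ± 1.96 sd on an implicated gPC form the positive/negative heavy-loader
sets.

## Enrichment

Terms are tested with the upper-tail hypergeometric probability
P(X ≥ k) of the observed query/term overlap (the observed count is
included, which is the standard one-sided enrichment convention).
Annotation records need E-value strictly below 1e-10; records without an
E-value are dropped unless explicitly kept. The default correction
multiplies p by the universe gene count — an unconventional scheme
implemented as the source procedure states it — with term-count Bonferroni
and Benjamini–Hochberg as clearly labeled alternatives. The universe is
the set of filter-surviving genes that carry at least one surviving
annotation record. Parent-term propagation for ontology-style inputs is
deliberately not performed.

## The synthetic generator

The generator emulates: blocked factorial metadata with per-sample
sampling datetimes (10:00–14:00, block order); hourly weather with
seasonal and diurnal temperature structure, cloud-modulated radiation,
humidity anti-correlated with temperature, and a middle season that is
+3 °C warmer, higher in evapotranspiration, and more variable in humidity;
NB counts with log₂µ = baseline + planted effects + rootstock-specific
slope × environment index + library factor, where the environment index is
the standardized day-mean temperature of the sampling day (a documented
stand-in for the first environmental PC, so recovery tests know the
planted axis); and an annotation in which one term is enriched among
rootstock-responsive genes with odds 20 — chosen so the planted term is
decisively enriched against ~40-gene term-size noise — and 20% of records
carry E-values above the 1e-10 cutoff to exercise the filter.

Planted effect defaults: 5% of genes carry a rootstock log₂-fold of 1.5
distributed over four archetype patterns (up-in-grafted, down-in-grafted,
up-in-one, split); 30%/20%/20% carry tissue/year/phenology effects
(log₂-fold 2/1/1); 5% carry rootstock-specific environment slopes of ±1
log₂-fold per SD of the index in the cross pattern (own-rooted and one
rootstock positive, the other two negative). Dispersion trend (a₀, a₁) =
(0.1, 1); library factors lognormal with σ = 0.3. Effect sizes are chosen
for test power, not biological fidelity — no field estimates of rootstock
effect sizes exist to calibrate against.

What the generator does **not** emulate: gene–gene correlation beyond the
planted patterns, batch or lane effects, count outliers, spatial field
structure, 3′-bias or gene-length effects, and any weather feature
cross-correlation beyond the built-in temperature couplings. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to everything real data can do.

## Problem sizes and determinism

Default scale is 2,000 genes × 204 samples (3 blocks, 1 vine), which runs
the full pipeline in well under a minute; the test suite uses smaller grids
and epoch counts (e.g. 6 × 6 maps, 30–60 epochs, 50–100 simulation
replicates) chosen so the whole suite completes in about a minute while
keeping Monte-Carlo error comfortably inside the asserted margins. All
randomness flows from explicit seeds (numpy `default_rng`); identical
config + seed gives bit-identical counts, codebooks, and output files.

## Known limitations

* Dispersion estimation is marginal method-of-moments, not GLM-based;
  strong design effects inflate the fitted a₀ (see above).
* The sequential-SS convention makes rootstock fractions mildly dependent
  on term order in unbalanced designs; the order is fixed and documented,
  and a partial-SS variant is not currently implemented.
* Tukey contrasts assume homoscedastic residuals across rootstocks.
* The SOM node count is fixed by configuration; no grid-size selection is
  attempted.
* Weather QC is limited to the tolerated-missing-fraction rule; no gap
  filling.
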