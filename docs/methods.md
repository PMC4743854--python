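# Methods

This note records the statistical model behind `floradiv`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Trait model and harmonisation

A flora is a species × trait matrix with five data types: continuous,
binary, ordinal, nominal, and multichoice (a set of nominal levels, e.g. a
dispersal syndrome `{animal, wind}`).  Raw observations are aggregated per
species — continuous traits by their **median** (robust to outliers),
ordinal traits by the **mean of level scores** (replicate counts for ordinal
data are typically low, and the mean preserves between-level information),
categorical traits by their **mode**.  Mode ties are resolved toward the
level declared earliest in the trait dictionary, which makes aggregation
deterministic; ordinal aggregates are kept as non-integer scores rather than
rounded back to levels, and downstream code treats ordinal traits as
quantitative scores throughout.

Missing quantitative cells are imputed with the mean of congeneric species
when at least one genus donor exists; categorical traits are never imputed.
Cell provenance (raw / aggregated / imputed) is tracked per cell.  The
missing marker is `pandas.NA`, distinct from every valid level code and
number.

Before analysis, traits invariant within the analysis group are dropped
(they carry no information and break standardisation), declared log/sqrt
transforms are applied to continuous traits, and quantitative traits are
z-standardised (mean 0, sd 1, ddof = 1) over non-missing entries.  Species
occurring on both continents carry the label `both` and are included in both
continents' groups; in the permutation tests this is realised by duplicating
their dissimilarity rows under per-continent aliases so that group labels
remain a partition.

## Gower dissimilarity

d(i,j) = Σₖ wₖ δₖ(i,j) / Σₖ wₖ, with wₖ = 1 iff both species have trait k
observed (pairwise deletion with weight renormalisation).  Per-trait
contributions: quantitative |a−b| / rangeₖ with the range taken once over
the full analysis set; binary and nominal simple mismatch (shared absence
counts as agreement — the binary traits encode states, not presences);
multichoice Jaccard dissimilarity of the level sets.  All traits are equally
weighted.  Traits whose observed values are constant are excluded from the
weighted mean entirely (weight 0 — the classical zero-range rule extended to
categorical types), which makes the coefficient exactly invariant to the
presence of uninformative traits.

By default the element-wise **square root** of the dissimilarities is taken
before ordination and testing.  For complete data the Gower similarity
matrix is positive semi-definite and √d is then exactly Euclidean; with
missing-data weighting this can fail, so embeddability is re-checked from
the smallest eigenvalue of the doubly centred −½D²-matrix and recorded on
the result.  A configuration switch allows raw Gower dissimilarities
instead; Lingoes and Cailliez corrections are available in `pcoa()` for
genuinely non-embeddable input but are off by default, since √d already
targets embeddability.

## Ordination

Classical scaling: eigendecomposition of B = −½ J D² J.  Eigenvalues within
±n·ε·λ_max of zero are treated as null; positive axes are scaled by √λ and
negative axes are retained as *imaginary* coordinates scaled by √|λ|.
Variance explained is reported per real axis as its share of the positive
eigenvalue sum.

Trait vectors for biplots are Pearson correlations of each quantitative
trait and each dummy-coded categorical level with the first two axis score
vectors, computed over the species where the trait is observed.  The
permutation p-value shuffles the trait vector and uses the maximum |r|
across the fitted axes as its statistic (999 permutations by default, the
package-wide convention).  Reported vectors are filtered to p ≤ 0.001 and
max |loading| ≥ 0.25; with 999 permutations and the add-one p-value
convention the smallest attainable p is exactly 0.001, so the threshold is
inclusive.

Trait-space occupation per group is summarised by a 2-D Gaussian kernel
density on the first two axes, evaluated on one shared lattice (all points
± 3 marginal bandwidths) so that group surfaces are directly comparable.
Bandwidths use Silverman's multivariate rule on the full sample covariance,
giving oriented kernels; this is the standard, robust scipy-backed choice
and behaves well down to the smallest group sizes the pipeline meets
(n ≈ 10).  Groups with fewer than 3 members are skipped.

## Diversity indices

**FDis** is the unweighted mean distance of an assemblage's species to their
centroid, computed in the principal-coordinate embedding with the standard
negative-eigenvalue correction: squared distances on imaginary axes are
subtracted from squared distances on real axes and the result floored at
zero.  For complete embeddable data this equals the plain Euclidean
computation; for non-embeddable input it matches the identity
dᵢ² = (1/n)Σⱼ d²ᵢⱼ − (1/n²)Σ_{j<k} d²ⱼₖ used by the dispersion test, so the
index and the test see the same geometry.

**FRic** is the convex-hull (quickhull) volume on the first *m* real axes.
It is undefined for assemblages with ≤ m species, and degenerate
(affinely dependent) point sets report volume 0 with a flag.  The default
axis count is min(min-richness − 1, number of real axes, 6), fixed across a
comparison set so volumes are commensurable; the cap of 6 keeps hulls
well-conditioned at the pool sizes involved.  FRic is reported both raw and
as a fraction of the pooled two-continent hull, the latter being the default
comparison quantity because raw hull volumes across clades embedded in
different spaces are not comparable.

## Permutation tests

Both tests operate on the (square-rooted) Gower dissimilarities with group =
continent and use the add-one, upper-tail p-value
p = (#{F* ≥ F} + 1)/(n_perm + 1), so p is never 0 and equals 1/(n_perm+1)
at best.  Default n_perm = 999 with a recorded seed.

* **Homogeneity of multivariate dispersions** (diversity-change hypothesis):
  distances of every species to its own-group centroid via the identity
  above, multiplied by √(n_g/(n_g−1)) to correct the downward bias of
  distances to an *estimated* centroid in small groups; observed F from a
  one-way ANOVA on these distances; permutation distribution from permuting
  the group labels of the fixed distances (distances are not recomputed per
  permutation, the standard practice for this test).  The statistic
  reproduces R `vegan::betadisper(..., type = "centroid",
  bias.adjust = TRUE)` to 1e−6 on Euclidean fixtures (cross-checked in the
  test suite).
* **perMANOVA** (identity-change hypothesis): SS_total = (1/N)Σ_{i<j} d²ᵢⱼ,
  SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²ᵢⱼ, pseudo-F =
  (SS_between/(g−1))/(SS_within/(N−g)); raw group labels are permuted and
  the sums recomputed per permutation.  On univariate Euclidean data the
  pseudo-F equals the classical one-way ANOVA F (machine precision), and the
  statistic matches both `vegan::adonis2` and scikit-bio's implementation.

Empirical calibration (two exchangeable groups of 40, 3-D Gaussian scores,
199 permutations, 500 datasets, computed by `scripts/acceptance.py` and
asserted in the test suite): type-I error ≈ 0.04–0.05 for perMANOVA (the
permutation test is exact by construction) and ≈ 0.05 for the dispersion
test, which is known to be slightly anti-conservative for very small groups
because the permuted distances keep the observed centroids; group sizes of a
few dozen, as in the analyses here, are comfortably calibrated.

Spatial non-independence of neighbouring grid cells is deliberately not
modelled: the inferential tests run at the species level, and the grid-scale
richness-FDis comparison is descriptive.

## Geospatial conventions

Rasters are numpy arrays on a WGS84 lon/lat `GridSpec` with cell-center
registration, half-open cell intervals [west, east) × [south, north), and
0-based row-major indexing from the north-west corner; plain-text I/O uses
the ESRI ASCII grid format, and range geometries are shapely polygons
(GeoJSON/WKT).  A cell belongs to a range iff its center lies inside the
polygon (deterministic and vertex-order-invariant); an area-overlap rule is
available behind configuration.  Cells with elevation strictly above 1000 m
are excluded (boundary cells kept).  Climatically similar regions come from
a PCA of the standardised cell × 19-layer climate matrix pooled over both
continents; cells are assigned to the four sign-quadrants of (PC1, PC2)
about the pooled score medians.  The quadrant rule is the default because it
is parameter-free and reproducible; k-means on the score pairs (fixed seed)
is available as an alternative, and the rule used is recorded in the region
mask's metadata.  The temperate-zone mask is an *input* raster, so alternate
climate classifications are simply alternative masks.

## Synthetic flora generator

The generator emulates the study design so every stage is testable without
compiled trait databases or digitised range maps:

* **Pools** (defaults): 126 + 56 angiosperms and 28 + 10 gymnosperms on the
  two continents plus one gymnosperm shared between both, i.e. per-continent
  gymnosperm subsets of 29 and 11 species.  Genera are drawn within clades
  with mean size ≈ 4 and ≈ 8% monotypic genera.
* **Traits**: a 26-trait dictionary with realistic names, units and levels —
  7 continuous, 4 binary, 9 ordinal, 4 nominal, 2 multichoice.  Species load
  on two latent strategy axes (an acquisitive–conservative axis and an
  overstorey–understorey axis); each trait is a random unit-norm projection
  of the latents plus noise (sd 0.5), thresholded at empirical quantiles
  into levels for categorical traits.  Genus effects contribute 0.6 sd of
  the latent variance, which is what makes genus-mean imputation
  informative.  Gymnosperms are offset by 1.5 sd on the second latent axis,
  and four categorical traits (wood porosity, leaf compoundness, tracheid
  presence, nitrogen fixation) are held constant within gymnosperms, so the
  invariant-trait filter reproduces a 26 → 22 reduction for that clade; the
  generator guarantees every other trait varies within each clade.
* **Missingness**: 14% of cells, completely at random by default (a
  genus-clustered mode exists to stress imputation).  With the default genus
  structure, genus-mean imputation of the 16 quantitative traits brings
  missingness to ≈ 6% (singleton genera and all-missing genus/trait
  combinations retain their gaps).
* **Geography**: one lon/lat grid (0.25° cells by default — coarser than 5
  arc minutes to keep simulations fast; the code is resolution-agnostic)
  split into two half-grid "continents"; 19 climate layers mixing a
  north–south and a within-continent east–west gradient with noise sd 0.3,
  so the first two PCA axes carry ≥ 80% (typically ≈ 90%) of the variance;
  a smooth two-ridge elevation surface crossing the 1000 m cutoff; a central
  latitude band as temperate mask; rectangular ranges with log-normal
  extents (median 3°, σ = 0.4) whose centre latitude is pulled toward the
  species' first latent score (strength 0.5), coupling traits to climate.
* **Null and alternative conditions**: by default both continents share one
  trait distribution (`continent_shift = 0`,
  `continent_dispersion_ratio = 1`) — the null under which the pipeline's
  p-values should be uniform.  The shifted scenario used in the power checks
  moves the European pool by 1.2 latent sd (detected by perMANOVA in
  essentially every run at 60 species per continent); the dispersion
  scenario scales European latent spread by 1.8.
* **Extinction scenarios**: random mode removes a uniform sample of the
  pool; directed mode removes all species beyond a quantile of a directing
  trait — the environmental-filter analogue of trimming the fringe of the
  trait cloud.  In paired simulations (60-species pools, one third removed,
  1000 replicates) directed extinction reduces the 2-D FRic hull strictly in
  every replicate and more than random extinction in ≈ 99% of them, while
  random thinning barely moves FDis — the quantitative embodiment of the
  diversity-change vs. identity-change dichotomy.

What the generator does **not** emulate: phylogenetically realistic trait
evolution (genus effects are exchangeable Gaussian, not tree-structured),
real range-shape complexity and spatial autocorrelation of occurrences,
climate–trait feedbacks beyond the single latitude pull, and
non-random (informative) missingness beyond the genus-clustered option.
Tests passing on synthetic floras therefore validate the *machinery* —
index algebra, test calibration, pipeline plumbing — not ecological
conclusions about any real flora.

## Numerical choices

* Eigenvalue sign tolerance in PCoA: |λ| ≤ n·ε·λ_max treated as zero.
* Hull degeneracy: volumes below 1e−12 (or Qhull failures on affinely
  dependent input) report 0 with a degeneracy flag rather than raising.
* Squared centroid distances are floored at 0 before the square root
  wherever imaginary-axis corrections apply.
* Permutation statistics are compared with a 1e−12 slack when counting
  F* ≥ F so exact ties (e.g. mirrored groups) count as exceedances.
* All generators and tests derive their randomness from explicit seeds;
  simulation problem sizes (500 calibration datasets, 1000 extinction
  pairs, 60-species pools) were chosen to keep each check to a couple of
  minutes on one CPU while leaving comfortable Monte-Carlo margins.

## Known limitations

* The dispersion test permutes fixed distances, so it inherits the mild
  small-group anti-conservatism discussed above.
* FRic in more than ~6 axes is numerically fragile and is capped by default.
* Multi-factor perMANOVA, strata, abundance-weighted indices (Rao's Q,
  FEve, FDiv) and phylogenetically informed distances are out of scope.
* Reprojection is not supported; all spatial inputs must share a geographic
  CRS and grid.
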