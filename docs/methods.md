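# Methods

## The model

The analysis treats a species' climatic niche as a fixed region in a 2-D
environmental space and asks how each range pixel's position within that
region changes between a current and a future climate.

**Environmental space.** The space is spanned by the first two principal
components of the climate variables, standardized per variable over the
calibration extent. Standardization (a correlation-matrix PCA) is used
because climate variables carry incommensurate units; the full variance
spectrum is reported for diagnostics but exactly two axes are retained.
PCA axis signs are arbitrary, so each loading column is flipped to make
its largest-magnitude element positive — projections are then
deterministic. The calibration is *frozen*: future climate is projected
through the same means, SDs and loadings. This is the numerical expression
of the niche-stability assumption — the niche envelope itself is taken to
be fixed over the projection horizon — together with niche filling (the
species occupies its suitable climate within the current range; no
expansion outside the range is mapped).

**Niche margin.** The occupied niche is estimated by a Gaussian KDE of the
species' range-pixel scores, computed by binning the scores onto an R×R
grid and convolving with a separable Gaussian kernel. Bandwidth is
Silverman's rule per axis (`sd · n^(−1/6)`), the standard choice for 2-D
environmental-space densities; pixels are equally weighted (the analysis
projects every occupied pixel, not occurrence densities). The margin at
quantile q = 0.99 is the boundary of the **highest-density region**
holding 99% of KDE mass: cells are ranked by density, mass is accumulated,
and the level at which accumulated mass reaches q defines the region. This
reading is well defined for multimodal densities; an alternative rule
(density level at the 1 % quantile of point-wise densities,
`margin_rule="density_quantile"`) is kept for comparison. Contours are
extracted at that level with marching squares; the density grid is
zero-padded by one cell first so every contour closes even when the region
touches the grid edge, and the grid is auto-expanded once (with a warning)
if the region reaches the boundary. The niche centroid is the
density-weighted mean of the region; for fragmented regions it is taken on
the highest-mass connected component (logged prominently), while the
margin itself is the union of all components.

**NMI.** For a score z, the index is `1 − ‖z − c‖/‖m − c‖` with m the
*outermost* crossing of the centroid ray through z with the margin
polylines — the outermost crossing makes the definition unambiguous for
non-convex margins. Interior values are clamped to [0, 1] (clamp events
logged); z = c gives 1 without a ray; rays that miss the margin entirely
(possible only for degenerate contours) yield a missing value and are
logged. A nearest-distance variant — signed distance to the margin
normalized by the centroid's nearest distance — is available via
`method="nearest"`; the radial form is the default because it guarantees
the 0-to-1 interior scale.

**Transitions.** With threshold τ (default 0.25, absolute; a quantile mode
cuts the lowest τ fraction of the species' global current-range NMI and
freezes that cut for the future period), each current-range pixel gets one
category: currently marginal pixels are trailing (ΔNMI < 0), leading
(ΔNMI > 0) or stable (ΔNMI = 0 — edges are defined by strict change);
currently core pixels whose future NMI drops into (0, τ) are newly
marginal; any pixel with future NMI ≤ 0 is a loss (from marginal or core
according to its current state), and loss takes precedence over edge
labels. Current-range pixels that already sit at or outside the margin
(NMI ≤ 0) count as marginal.

**Aggregation.** Joint-marginality maps count, per pixel, the species in a
category. Country tallies count a species toward a country and metric when
at least one pixel (configurable minimum) of the metric's categories has
its center inside the clipped country polygon; border ties resolve to the
first country in id order (deterministic). "Future trailing" is the union
of trailing and newly marginal pixels; "loss" covers both loss
subcategories. Species-group lists are configuration.

**Effort regression.** Country GME counts are modelled with a log link:
area enters standardized (per SD), per-capita GDP as an orthonormal
quadratic polynomial (centered QR construction; a raw-polynomial option
exists). The negative-binomial dispersion α (NB2, var = μ + αμ²) is
estimated by maximum likelihood, then the GLM is fit at that α; when NB
gains no appreciable likelihood over Poisson (< 10⁻³), α is collapsed to
the boundary (10⁻⁸), making the Poisson limit explicit rather than leaving
the optimizer stalled near zero. The null model for L₀ is the
intercept-only fit of the same family and excludes spatial filters. The
Veall–Zimmermann pseudo-R² is the Aldrich–Nelson measure normalized by its
bound: with λ = 2(L₁ − L₀), `R² = [λ/(λ+n)] / [−2L₀/(−2L₀+n)]`, clipped to
[0, 1].

**Spatial screening.** Moran's I is computed on deviance residuals in
contiguous great-circle distance bands (300 km wide to 1,500 km; mean
Earth radius 6,371 km) with binary within-band weights; significance is a
two-sided permutation test around the permutation-null expectation
−1/(n−1), with 999 relabelings by default and an explicit seed. Moran's
Eigenvector Maps come from the neighbour graph of country centroids: pairs
within a link threshold (default: the smallest distance at which every
country has at least one neighbour) are linked, weights are
row-standardized, symmetrized and double-centered, and the eigenvectors
(near-zero eigenvalues dropped, signs fixed deterministically) form the
basis. Positive-eigenvalue vectors are added one at a time, in decreasing
eigenvalue order, as linear terms kept regardless of their own
significance, until every band p-value rounded to two decimals is ≥ 0.05;
exhausting the basis warns and returns the fullest fit. Known outliers
(e.g. a single very large country with zero effort) are handled by a
caller-supplied exclusion list, never hard-coded. A Hermite count family
is reserved in the interface but intentionally not implemented.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not real geography. Climate variables (default 19) are unit-variance
Gaussian random fields (kernel-convolved white noise, correlation length
`smoothness`) plus random linear latitude/longitude gradients whose
amplitude scales with the smoothness, so the smoothness → 0 limit is pure
white noise; PCA must recover the induced cross-variable structure just as
it recovers real climatic gradients. Scenarios are exact per-variable
affine updates (future = shift + scale × current). Countries are a Voronoi
tiling of uniform random seeds clipped to the extent (irregular but
deterministic); areas use an equirectangular approximation, adequate at
desk scale, and GDP is log-normal. Land cover is the arg-max of smoothed
categorical propensity fields, giving spatially coherent classes whose
filter removes a controllable pixel fraction. Species ranges are
Mahalanobis envelopes around a known centroid in the latent space (the
first two standardized PCs of current climate), with occurrences drawn
from range pixels with weight exp(−d²/2). Project counts are NB2 draws
(gamma–Poisson; dispersion ∞ = Poisson) from a log-mean linear in the same
design matrix the fit uses, optionally contaminated along the leading
Moran eigenvector; each count expands into a fully populated Category II
record, and controlled numbers of invalid and Category I records carry
intended labels for recovery tests. All randomness derives from one master
seed through CRC-named substreams, so outputs are byte-identical across
runs and processes.

What the generator does **not** emulate: real bioclimatic covariance
structure, coastlines and sea masks, dispersal or occupancy dynamics,
range-map error, or the documentary messiness of real project
submissions. Passing tests therefore demonstrate correctness of the
computations and recovery of known structure — not that real-data
reproductions will match published values, which additionally depend on
the exact input data.

## Numerical choices and degenerate inputs

- KDE grid: default R = 200 (150 in the batch pipeline) with 10 % padding
  plus three bandwidths of kernel tail; the binned-KDE mass is
  renormalized after convolution.
- Enclosed mass of the reported region equals q within one cell's mass
  (≤ 10⁻³ at default resolution).
- Duplicate score pairs are allowed (the KDE handles ties); all-identical
  scores raise a degenerate-niche error; fewer than 10 scores is an error.
- A constant climate variable raises an error naming it; fewer calibration
  pixels than variables warns and fits on the available rank; missing
  climate values propagate to missing scores (counted and logged), never
  silently dropped.
- ΔNMI = 0 is "stable", not an edge; categories are mutually exclusive and
  exhaustive over finite-NMI pixels.
- Rigid motions: NMI is translation-equivariant to machine precision;
  under rotation the axis-aligned KDE grid limits agreement to the cell
  scale (verified at 0.02 with an isotropic kernel), which is the
  discretization cost of the grid-based margin.
- The NB-vs-Poisson boundary collapse (above) makes coefficient agreement
  on equidispersed data exact to ~10⁻⁵ at moderate n.
- Permutation p-values use the add-one convention
  (1 + #extreme)/(n_perm + 1).

## Problem sizes in tests and the acceptance script

Synthetic worlds of 60×60–100×100 pixels with 2–10 species; Gaussian
niche recovery at n = 20,000 scores on a 250-cell grid (margin sampling
noise at n = 5,000 leaves ~0.02 RMSE, dominated by the margin's radial
wobble, and halves at the larger size); GLM recovery over 100 replicate
tables of 500 countries; Moran type-I calibration over 200 replicates of
30 units with 199 permutations. These sizes were chosen so each suite
runs in minutes on one CPU while leaving Monte-Carlo error well inside
the asserted bounds.

## Known limitations

- The margin is a grid contour: sub-cell precision is not claimed, and
  strongly fragmented niches place the centroid on the dominant component
  only.
- The radial NMI assumes the margin is reachable along the centroid ray;
  for extremely non-star-shaped regions the outermost-crossing rule with
  interior clamping is a convention, not a theorem.
- Country areas in the generator are approximate (equirectangular); real
  analyses should supply measured areas.
- The two published-data reproductions (deposited project table;
  country-level regression statistics) require the study's data deposits,
  which are not redistributed; the corresponding tests document the
  expected schemas and run only when the files are supplied.
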