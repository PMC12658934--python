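# Methods

`beecorridors` implements a landscape-connectivity analysis for wild-bee
communities sampled along roadsides and other linear habitats: it maps
seminatural linear landscape structures (LLS), treats their local density
as a conductance surface for bee movement, routes least-cost paths (LCPs)
between sampling sites, and asks (i) whether bee species richness
increases with the length of LLS around a site and (ii) whether
between-site community similarity is better explained by corridor
distance than by geographic distance.

## Mapping seminatural LLS

The land-cover model is an integer raster in the CLC+ backbone
convention (11 classes at 10 m). Four class groups define seminatural
patches: forest (codes 2, 3), low woody vegetation (5), permanent
herbaceous (6), and sparsely vegetated areas (9). Each group is
polygonized separately; every interior raster face between a member and a
non-member cell becomes one unit boundary segment, and the union over
groups is deduplicated, so a forest–grassland face contributes one
segment, not two. Two line maps are produced: all seminatural LLS and
forest edges only; nonforest LLS length is the difference of the two
(floored at zero).

Design choices where the procedure was genuinely open:

* **Raster-border faces are not edges.** A patch truncated by the study
  area boundary contributes no segment there; this avoids artificial
  corridors along the raster frame. Faces adjacent to nodata cells are
  excluded for the same reason.
* **Per-group polygonization, then union.** The alternative — merging all
  seminatural classes into one mask before boundary extraction — would
  erase internal forest–grassland edges. We flag this as an open choice;
  the per-group variant retains those edges, which is consistent with
  treating each patch type as habitat in its own right.
* **Closed-cell rasterization.** A cell is marked when a segment
  intersects its closed square, so a segment lying exactly on a shared
  cell edge marks both cells, and a segment endpoint on a grid corner
  marks all touching cells. This is deterministic and orientation-free.
* **Radius metrics.** LLS length within a radius uses exact analytic
  clipping of each segment to the disc (one quadratic per segment).
  Grassland proportion uses cell-center membership, unbiased at 10 m
  resolution; nodata cells are excluded from numerator and denominator.

## Corridors

The fine binary edge maps are aggregated by an integer factor (default
10) into a proportion grid; aggregation conserves the fine 1-cell count
exactly (zero-padding at the top/right when dimensions do not divide).
On the coarse grid, movement is modelled on the 8-neighbor graph. The
conductance of a step between cells i and j is `mean(x_i, x_j) / d_ij`
with `d_ij ∈ {1, √2}` cell units, and the edge weight minimized is the
cost `1/conductance`, so costs grow without bound as the local share of
linear habitat drops. Zero proportions are floored at `eps = 1e-6`
before averaging: the reciprocal transform is undefined at true zeros,
the floor keeps the graph connected, and any detour through cells with
positive habitat share is preferred over crossing empty matrix.

Per least-cost path we report two metrics: geometric **length** of the
center-to-center polyline (rook steps `cell_size`, diagonal steps
`√2 · cell_size`), and accumulated **cost**, the sum of `(1 − x)` over
the path's cells, endpoints included and each visited cell counted once.
Sites are snapped to the coarse cell containing them, accepting a
discretization error of at most one cell diagonal; this is why the
length-dominance invariant (`LCP length ≥ geographic distance`) is only
asserted up to that slack. Routing uses Dijkstra on a sparse CSR graph
(`scipy.sparse.csgraph`); ties between equal-cost paths are resolved by
the algorithm's fixed internal scan order, which is deterministic for a
given grid. Pair distances are computed for all unordered within-country
site pairs, one Dijkstra sweep per distinct source cell.

## Community similarity

Occurrence tables are wide site × species count matrices. Curation drops
kleptoparasitic species (their distribution tracks hosts rather than
habitat) and pools cryptic complexes — e.g. *Bombus sensu stricto* —
into one morphospecies column; retained counts are conserved.

Similarity between two sites is `1 − BC` with the *binary* Bray–Curtis
dissimilarity `(A + B − 2J)/(A + B)` (presence richnesses A, B; shared
species J), i.e. similarity `2J/(A+B)`. The solitary-bee similarity adds
a dummy species present at every site (A, B, J each +1), which keeps the
index defined for empty communities and damps zero inflation in this
sparse group; the all-bee and plant similarities are computed without
the dummy, and an empty pair without the dummy propagates as missing
(never silently 0) and is dropped from model fits with a logged count.
The plant-richness covariate of a site is its species count in the plant
occurrence table (plants with at least one recorded bee interaction),
so covariate and plant-similarity response describe the same data.

## Richness models

Bee species richness per site is fit with Poisson GLMs (log link, IRLS
via statsmodels, deviance tolerance 1e-8):

    richness ~ log(LLS length + 1 m) + plant richness
               + log(grassland proportion + 1e-4) + country
               + x + y   (coordinates centered/scaled)

one fit per radius (250…1500 m) and LLS type (all / forest / nonforest);
the radius minimizing AICc wins (ties prefer the smaller radius). The
`+1 m` and `+1e-4` offsets guard log-transforms of quantities that can
legitimately be zero; coordinate scaling affects coefficients only, not
deviance or AICc differences. Diagnostics: Moran's I on Pearson
residuals with inverse-distance, row-standardized weights (expectation
−1/(n−1); randomization variance, i.e. the kurtosis-corrected form used
by `ape::Moran.I`; two-sided normal p), and a Pearson χ²/df
overdispersion ratio flagged above 1.5. Term significance uses drop-one
likelihood-ratio tests, which for Poisson equal the deviance difference.

## Distance-decay models

The pairwise response (bee similarity of a site pair) is modelled with a
crossed-random-intercept mixed model

    y_k = β₀ + β_d · distance_k + β₁ plantSR_i + β₂ plantSR_j
          + β₃ plantSR_i·plantSR_j + β₄ plant similarity
          + u[site_i(k)] + v[site_j(k)] + ε_k

with independent intercepts for the first and second site of each pair
absorbing site-level mean differences. Estimation is ML:

* **Gaussian residuals:** the random effects integrate out exactly.
  β and σ²_e are profiled; the optimizer searches the two variance
  ratios. All W-weighted products are computed through the Woodbury
  identity on the q × q capacitance matrix (q = number of site levels),
  so a likelihood evaluation is O(q³) regardless of the number of pairs.
  The fit reproduces `lme4::lmer(..., REML = FALSE)` to ~1e-6 on a
  frozen fixture.
* **Student-t residuals** (the heavier-tailed family used for the
  reported fits): the marginal likelihood is approximated by a Laplace
  integral over the random effects. The inner mode finder is Fisher
  scoring with the expected t-weight (ν+1)/(ν+3) — always positive
  definite — with step halving; the Laplace determinant uses the true
  Hessian at the mode (falling back to the Fisher information if the
  Hessian is locally indefinite). The t degrees of freedom are estimated
  on the log scale with floor 2.01 (finite variance), starting at 5.
  In the large-ν limit the Laplace fit reproduces the exact Gaussian
  likelihood, which the tests use as an oracle for the shared code path.

AICc counts fixed effects + 2 variance components + the residual scale,
plus the t df when estimated. This convention is stated because ΔAICc
between families depends on it. Variance components may collapse to
numerical zero (boundary fit, flagged); a fit with both variances forced
to zero equals the OLS solution exactly.

Candidate distance measures — geographic, LCP length and LCP cost on
each of the two LLS maps — are compared per country against a null model
without a distance term, by AICc, with ΔAICc reported relative to the
geographic-distance model.

**Threshold sensitivity.** Because similarity can stop declining beyond
some distance (spatially clustered land use reintroduces similar species
pools), each country's pairs are scanned over maximum-distance
thresholds (default 10–105 km in 5 km steps): at each threshold a linear
and a quadratic distance model are fit and `ΔAICc = AICc_linear −
AICc_quadratic` recorded; the chosen threshold is the largest at which
the linear model wins (Δ < 0) or ties (|Δ| < 2). Thresholds with fewer
than 30 pairs are skipped and logged. The chosen per-country thresholds
cap the pair sets used in the distance-model comparison.

## Synthetic data generator

The generator produces a full toy study so the pipeline runs end-to-end
with no downloads. What it emulates, and how the defaults were chosen:

* **Landscape:** a Gaussian random field (smoothing scale 300 m)
  thresholded by quantiles into CLC+-style classes (cropland matrix
  ~42%, forest ~24%, herbaceous 16%, low woody 8%, sparse 5%, sealed
  5%), giving contiguous patches whose boundaries form connected linear
  networks. The 300 m patch scale was calibrated so that least-cost
  corridor lengths run ~1.4–1.5× geographic distance on average with
  occasional 2–3× detours — the regime observed in the intensively
  managed field landscapes this emulates. Default extent 10 × 10 km.
* **Sites:** rejection-sampled with ≥1 km pairwise separation, 20 per
  country; the two countries are the western/eastern halves so the
  within-country pair restriction is meaningful.
* **Communities:** each species has a random home site and occupies site
  j with probability `p₀ · exp(−d(home, j)/λ_group) · quality_j`,
  Bernoulli-thinned, counts Poisson(1)+1 where present. `d` is the LCP
  length on the seminatural-LLS map ("corridor" truth) or the Euclidean
  distance ("euclidean" truth — the control mode for selection-
  specificity tests). Decay scales: solitary bees λ = 4 km, bumblebees
  λ = 10 km (poorer dispersers decay faster; scales sized to the 10 km
  extent), plants λ = 20 km with Euclidean decay. Site quality combines
  relative plant richness (exponent 0.5) and relative local LLS length
  within 1.5 km (exponent 0.3), creating the richness–LLS and
  richness–plant effects the richness models should recover; `p₀ =
  0.95`. Kleptoparasites (8 species) and one three-member cryptic
  bumblebee complex exercise the curation step. The defaults yield ~8–11
  species per site from a pool of ~60, comparable to roadside bee
  surveys.
* **Not emulated:** sampling phenology and repeat rounds, observation
  effort beyond Bernoulli thinning, climate gradients, and any
  distinction between foraging and natal dispersal. Passing tests
  therefore demonstrate the *machinery* (geometry, routing, similarity,
  likelihoods, selection behavior) under a plausible generative model,
  not field realism.

Because the corridor-truth generator uses the same LCP engine the
analysis uses, model-selection tests are comparative (LCP model vs
geographic model on identical data), and an independent Euclidean-truth
mode provides the specificity control.

## Problem sizes and numerical choices

Simulation-based tests run at reduced raster resolution (10 × 10 km at
20 m cells, aggregated to 200 m corridor cells) with the default 20
sites per country; this preserves the study geometry (site separation,
corridor detour statistics, ~380 within-country pairs) at a fraction of
the 10 m compute. The test suite documents each problem size where it is
used. Key tolerances: Dijkstra-vs-enumeration and conservation
invariants are exact (1e-12 relative); the lme4 cross-check is 1e-6 to
2e-5; the Laplace-vs-exact Gaussian check allows 0.25 log-likelihood
units; type-I calibration of the LRT uses ±2 binomial SE around 5% over
1000 fits.

Degenerate inputs: a constant response yields zero slope and boundary
variances; an empty class set covering the whole raster yields an empty
line set (not an error); `src == dst` corridors are single-cell paths
with cost `1 − x`; empty similarity pairs are missing unless the dummy
species is used.

## Known limitations

* The conductance surface is binary-habitat-derived; resistance
  differences among matrix types (e.g. extensively vs intensively
  managed grassland) are not modelled.
* Corridor length is measured along the minimum-*cost* path, so the
  length of that path is not itself a metric and can occasionally
  violate the triangle inequality across cell-snapped endpoints.
* The t-family Laplace approximation is not exact for small ν; its
  accuracy is checked only in the Gaussian limit and against fit
  behavior on heavy-tailed simulations.
* Bray–Curtis on presence–absence with small communities is noisy, and
  undersampling inflates dissimilarity; the generator reproduces this
  noise level but no observation-effort correction is applied.
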