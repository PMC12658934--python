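# beecorridors

Habitat-connectivity analysis for wild-bee communities in intensively
managed landscapes. Seminatural **linear landscape structures (LLS)** —
forest edges, grassland margins, verges around sparsely vegetated ground
— are both habitat and plausible dispersal corridors for bees. This
package derives LLS line maps from a categorical land-cover raster,
builds a conductance surface from their local density, routes
**least-cost paths (LCPs)** between sampling sites, and tests two
hypotheses:

1. **Habitat provision.** Bee species richness at a site increases with
   the length of seminatural LLS within its foraging range, controlling
   for local plant richness, grassland cover, country, and location:

   `richness ~ log(LLS_radius) + plantSR + log(grassland_radius) + country + x + y`

   (Poisson GLM per radius 250–1500 m; spatial scale selected by AICc;
   Moran's I and dispersion diagnostics; drop-one likelihood-ratio
   tests.)

2. **Dispersal corridors.** Pairwise community similarity — binary
   Bray–Curtis similarity `2J/(A+B)` — declines faster with corridor
   distance than with geographic distance. For each within-country site
   pair,

   `sim_ij ~ distance_ij + plantSR_i × plantSR_j + plant_sim_ij + (1|site_i) + (1|site_j)`

   is fit as a crossed-random-intercept mixed model (Gaussian or
   Student-t residuals, ML; exact marginal likelihood for the Gaussian
   family, Laplace approximation for the t family), and six candidate
   models — null, geographic distance, LCP length and LCP cost on the
   all-LLS and forest-edge maps — are compared by AICc.

A seeded synthetic-study generator (patchy landscape, ≥1 km-separated
sites in two countries, bee occupancy decaying with corridor distance,
faster for solitary bees than bumblebees) makes the whole pipeline
runnable and testable end-to-end with no data download. See
`docs/methods.md` for the model details and design choices.

Intended users: landscape ecologists and conservation planners who want
reproducible LCP-based connectivity analyses on categorical land-cover
rasters, and method developers who need a fully synthetic test bed for
distance-decay inference.

## Worked example

```bash
beecorridors simulate --seed 1 --out demo/          # synthetic study
beecorridors pipeline \
  --landcover demo/landcover.asc --sites demo/sites.csv \
  --bees demo/bees.csv --plants demo/plants.csv --traits demo/traits.csv \
  --family gaussian --out demo/run/
```

or, in Python, the equivalent of what `scripts/acceptance.py --seed 1`
prints (10 × 10 km landscape, 20 sites per country, corridor-structured
occupancy):

```
bee_richness_mean                       11.08
bee_similarity_mean                     0.261
lcp_geo_length_ratio_mean               1.381
best_radius_all_lls_m                   1500
coef_log_lls_length                     0.858
lrt_p_lls_length                        8.7e-05
morans_i_p_best_model                   0.393
dispersion_ratio                        0.936
decay_slope_lcp_forest_all_bees         -0.0060
delta_aicc_geo_minus_best_lcp_all_bees  5.48
```

Reading these numbers: sites host on average ~11 bee species; corridors
tracking LLS run ~1.38× the straight-line distance; the richness–LLS
relationship is strongest at the 1500 m radius and the LLS-length term
is significant (LRT p ≈ 1e-4) with no residual spatial autocorrelation
(Moran's I p = 0.39) and no overdispersion (ratio 0.94); pairwise
similarity declines with forest-edge LCP length (slope −0.006 per km),
and the best LCP model beats the geographic-distance model by ~5.5 AICc
units — the corridor signal the scenario was generated with.

## Package layout

| module | contents |
| --- | --- |
| `beecorridors.landcover` | grid/line types, boundary extraction, rasterization, aggregation, radius metrics |
| `beecorridors.corridors` | conductance graph, Dijkstra LCPs, corridor metrics, pair distances |
| `beecorridors.community` | curation (parasites, cryptic complexes), richness, Bray–Curtis, pair table |
| `beecorridors.glmm` | crossed-random-intercept mixed models (Gaussian exact / Student-t Laplace) |
| `beecorridors.stats` | Poisson GLMs, AICc selection, LRT, Moran's I, dispersion, model comparison, sensitivity scan |
| `beecorridors.simulate` | seeded synthetic-study generator |
| `beecorridors.pipeline`, `beecorridors.cli` | orchestration, validation, `beecorridors` command |
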