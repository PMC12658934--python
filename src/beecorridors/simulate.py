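"""Seeded synthetic study generator.

Produces a complete toy study — patchy multi-class land-cover raster,
spatially separated sampling sites in two countries, plant communities,
and bee communities whose between-site similarity decays with corridor
distance — so that every stage of the pipeline runs end-to-end without
any data download.

The generative model mirrors the study design being analyzed:

* The landscape is a smoothed Gaussian random field thresholded into
  CLC+-style classes (cropland matrix with forest, grassland, low-woody
  and sparsely vegetated patches), so patch boundaries form connected
  linear structures.
* Sites are rejection-sampled with a minimum pairwise separation
  (default 1 km) and split spatially into a western and an eastern
  country.
* Each species gets a random home site and occupies site ``j`` with
  probability ``p0 * exp(-d(home, j) / lambda_group) * quality_j``
  (Bernoulli), where ``d`` is the least-cost-path length along
  seminatural LLS ("corridor" truth) or the Euclidean distance
  ("euclidean" truth), and ``quality_j`` increases with local plant
  richness and the length of seminatural LLS around the site.  Solitary
  bees get a shorter decay scale than bumblebees, so their similarity
  decays faster.  Kleptoparasitic species and one cryptic bumblebee
  complex are generated to exercise the curation step.

Identical seeds give bit-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import dijkstra

from beecorridors import landcover as lc
from beecorridors import raster_io
from beecorridors.corridors import build_graph, _trace, _path_from_nodes
from beecorridors.community import richness

#: class codes drawn, in threshold order (cropland matrix in the middle
#: of the field range so seminatural patches form distinct boundaries)
_CLASS_ORDER = (1, 7, 6, 5, 3, 2, 9)


@dataclass
class ScenarioConfig:
    """Tunable study conditions for the synthetic generator."""

    seed: int = 0
    n_rows: int = 1000
    n_cols: int = 1000
    cell_size: float = 10.0  # m; default landscape is 10 x 10 km
    class_weights: dict = field(
        default_factory=lambda: {1: 0.05, 7: 0.42, 6: 0.16, 5: 0.08, 3: 0.10, 2: 0.14, 9: 0.05}
    )
    smooth_sigma_m: float = 240.0  # patch size scale in meters; calibrated
    # so corridor lengths run ~1.4x geographic distance on average, the
    # regime reported for the field landscapes being emulated
    n_sites_per_country: int = 20
    min_separation_m: float = 1000.0
    margin_m: float = 300.0
    n_bumblebee: int = 12
    n_solitary: int = 40
    n_parasitic: int = 8
    n_plants: int = 30
    cryptic_complex_size: int = 3
    lambda_bumblebee_km: float = 10.0
    lambda_solitary_km: float = 4.0
    lambda_plants_km: float = 20.0
    p0: float = 0.95
    quality_effect: float = 0.5  # exponent on relative plant richness
    lls_effect: float = 0.3  # exponent on relative local LLS length
    plant_rate: float = 12.0  # mean plant species richness per site
    truth: str = "corridor"  # or "euclidean"
    aggregation_factor: int = 10
    eps: float = 1e-6
    radius_quality_m: float = 1500.0

    def __post_init__(self) -> None:
        total = sum(self.class_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class weights must sum to 1 (got {total})")
        if self.lambda_solitary_km <= 0 or self.lambda_bumblebee_km <= 0:
            raise ValueError("decay scales must be positive")
        if self.min_separation_m < 0:
            raise ValueError("min separation must be >= 0")
        if self.truth not in ("corridor", "euclidean"):
            raise ValueError("truth must be 'corridor' or 'euclidean'")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class ScenarioBundle:
    """All artifacts of one synthetic study."""

    config: ScenarioConfig
    landcover: lc.LandCoverGrid
    sites: pd.DataFrame
    occ_bees: pd.DataFrame
    occ_plants: pd.DataFrame
    traits: pd.DataFrame
    truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        raster_io.write_landcover(out / "landcover.asc", self.landcover)
        self.sites.to_csv(out / "sites.csv", index=False)
        _write_long(out / "bees.csv", self.occ_bees)
        _write_long(out / "plants.csv", self.occ_plants)
        self.traits.to_csv(out / "traits.csv", index=False)
        truth = dict(self.truth)
        truth["config"] = asdict(self.config)
        (out / "truth.json").write_text(json.dumps(truth, indent=2, default=float))


def _write_long(path, occ: pd.DataFrame) -> None:
    long = occ.stack()
    long = long[long > 0].rename("count").reset_index()
    long.columns = ["site", "species", "count"]
    long.to_csv(path, index=False)


def read_occurrences(path, site_ids=None, species=None) -> pd.DataFrame:
    """Read a long (site, species, count) CSV into the wide matrix form."""
    long = pd.read_csv(path)
    wide = long.pivot_table(index="site", columns="species", values="count",
                            aggfunc="sum", fill_value=0)
    if site_ids is not None:
        wide = wide.reindex(site_ids, fill_value=0)
    if species is not None:
        wide = wide.reindex(columns=species, fill_value=0)
    wide.columns.name = None
    wide.index.name = None
    return wide.astype(int)


def simulate_landscape(cfg: ScenarioConfig) -> lc.LandCoverGrid:
    """Threshold a smoothed random field into contiguous land-cover patches."""
    rng = cfg.rng(1)
    sigma_cells = cfg.smooth_sigma_m / cfg.cell_size
    fld = gaussian_filter(rng.standard_normal((cfg.n_rows, cfg.n_cols)), sigma_cells)
    codes = [c for c in _CLASS_ORDER if cfg.class_weights.get(c, 0.0) > 0]
    weights = [cfg.class_weights[c] for c in codes]
    cum = np.cumsum(weights)[:-1]
    cuts = np.quantile(fld, cum)
    idx = np.searchsorted(cuts, fld, side="right")
    values = np.asarray(codes, dtype=np.int64)[idx]
    return lc.LandCoverGrid(values, cfg.cell_size, origin=(0.0, 0.0))


def simulate_sites(cfg: ScenarioConfig, grid: lc.LandCoverGrid) -> pd.DataFrame:
    """Rejection-sample site locations with minimum pairwise separation.

    The western half of the landscape is country "NO", the eastern half
    "DK"; plant richness is drawn Poisson around a site-quality latent.
    """
    rng = cfg.rng(2)
    width = grid.shape[1] * grid.cell_size
    height = grid.shape[0] * grid.cell_size
    m = cfg.margin_m
    halves = {"NO": (m, width / 2 - m), "DK": (width / 2 + m, width - m)}
    if any(hi <= lo for lo, hi in halves.values()) or height - m <= m:
        raise RuntimeError(
            "could not place sites at the requested separation: landscape too "
            "small for the margins; reduce margin_m or enlarge the raster"
        )
    xs: list[float] = []
    ys: list[float] = []
    countries: list[str] = []
    attempts = 0
    for country, (x_lo, x_hi) in halves.items():
        placed = 0
        while placed < cfg.n_sites_per_country:
            attempts += 1
            if attempts > 100_000:
                raise RuntimeError(
                    "could not place sites at the requested separation; "
                    "reduce n_sites_per_country or min_separation_m"
                )
            x = rng.uniform(x_lo, x_hi)
            y = rng.uniform(m, height - m)
            if all((x - xa) ** 2 + (y - ya) ** 2 >= cfg.min_separation_m**2
                   for xa, ya in zip(xs, ys)):
                xs.append(x)
                ys.append(y)
                countries.append(country)
                placed += 1
    quality = rng.normal(0.0, 0.35, size=len(xs))
    plant_richness = rng.poisson(cfg.plant_rate * np.exp(quality))
    sites = pd.DataFrame(
        {
            "id": [f"S{k:03d}" for k in range(len(xs))],
            "x": xs,
            "y": ys,
            "country": countries,
            "plant_richness": plant_richness,
        }
    )
    sites.attrs["quality_latent"] = quality
    return sites


def _lls_proportion_grid(cfg: ScenarioConfig, grid: lc.LandCoverGrid,
                         class_sets) -> tuple[lc.LineSet, lc.ProportionGrid]:
    lines = lc.extract_boundaries(grid, class_sets)
    binary = lc.rasterize_lines(lines, grid.cell_size)
    return lines, lc.aggregate_proportion(binary, cfg.aggregation_factor)


def _lcp_length_matrix(prop: lc.ProportionGrid, sites: pd.DataFrame,
                       eps: float) -> np.ndarray:
    """Pairwise LCP lengths (km) between all sites on one proportion grid."""
    graph = build_graph(prop, eps=eps)
    nodes = [graph.node(prop.cell_of(float(r["x"]), float(r["y"])))
             for _, r in sites.iterrows()]
    n = len(nodes)
    out = np.zeros((n, n))
    uniq = sorted(set(nodes))
    _, preds = dijkstra(graph.costs, directed=False, indices=uniq,
                        return_predecessors=True)
    row_of = {s: k for k, s in enumerate(uniq)}
    for a in range(n):
        for b in range(a + 1, n):
            if nodes[a] == nodes[b]:
                continue
            seq = _trace(preds[row_of[nodes[a]]], nodes[a], nodes[b])
            path = _path_from_nodes(graph, seq)
            out[a, b] = out[b, a] = path.length / 1000.0
    return out


def _euclid_matrix(sites: pd.DataFrame) -> np.ndarray:
    xy = sites[["x", "y"]].to_numpy(float)
    return np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1)) / 1000.0


def simulate_communities(
    cfg: ScenarioConfig,
    sites: pd.DataFrame,
    grid: lc.LandCoverGrid,
    dist_km: np.ndarray | None = None,
    lls_lines: lc.LineSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw plant and bee occupancy with distance-decaying similarity.

    Returns ``(occ_bees, occ_plants, traits)``; ``dist_km`` is the
    between-site distance matrix driving bee occupancy decay (computed
    from the configured truth mode when omitted).
    """
    rng = cfg.rng(3)
    n_sites = len(sites)
    site_ids = sites["id"].to_list()

    if lls_lines is None:
        lls_lines = lc.extract_boundaries(grid, lc.SEMINATURAL_CLASS_SETS)
    if dist_km is None:
        if cfg.truth == "corridor":
            _, prop = _lls_proportion_grid(cfg, grid, lc.SEMINATURAL_CLASS_SETS)
            dist_km = _lcp_length_matrix(prop, sites, cfg.eps)
        else:
            dist_km = _euclid_matrix(sites)

    # site quality: relative local plant richness x relative LLS length
    lls_len = np.array(
        [lc.length_within_radius(lls_lines, (r["x"], r["y"]), cfg.radius_quality_m)
         for _, r in sites.iterrows()]
    )
    # plants first: decay over Euclidean distance, quality from the latent
    latent = sites.attrs.get("quality_latent", np.zeros(n_sites))
    qual_p = np.exp(latent)
    qual_p = (qual_p / qual_p.max()) ** cfg.quality_effect
    d_e = _euclid_matrix(sites)
    plants = {}
    for s in range(cfg.n_plants):
        name = f"P{s:03d}"
        home = rng.integers(n_sites)
        p = cfg.p0 * np.exp(-d_e[home] / cfg.lambda_plants_km) * qual_p
        occ = rng.random(n_sites) < p
        counts = np.where(occ, rng.poisson(1.0, n_sites) + 1, 0)
        plants[name] = counts
    occ_plants = pd.DataFrame(plants, index=site_ids)
    plant_sr = richness(occ_plants).to_numpy(float)

    qual = (plant_sr / max(plant_sr.max(), 1.0)) ** cfg.quality_effect
    if lls_len.max() > 0:
        qual = qual * (lls_len / lls_len.max()) ** cfg.lls_effect

    species: dict[str, np.ndarray] = {}
    trait_rows = []

    def draw_group(prefix, count, lam, group, parasitic):
        for s in range(count):
            name = f"{prefix}{s:03d}"
            home = rng.integers(n_sites)
            p = cfg.p0 * np.exp(-dist_km[home] / lam) * qual
            occ = rng.random(n_sites) < p
            counts = np.where(occ, rng.poisson(1.0, n_sites) + 1, 0)
            species[name] = counts
            complex_label = None
            if group == "bumblebee" and not parasitic and s < cfg.cryptic_complex_size:
                complex_label = "Bombus_sensu_stricto"
            trait_rows.append(
                {"species": name, "parasitic": parasitic, "group": group,
                 "cryptic_complex": complex_label}
            )

    draw_group("B", cfg.n_bumblebee, cfg.lambda_bumblebee_km, "bumblebee", False)
    draw_group("S", cfg.n_solitary, cfg.lambda_solitary_km, "solitary", False)
    draw_group("K", cfg.n_parasitic, cfg.lambda_solitary_km, "solitary", True)

    occ_bees = pd.DataFrame(species, index=site_ids)
    traits = pd.DataFrame(trait_rows)
    return occ_bees, occ_plants, traits


def generate_scenario(cfg: ScenarioConfig | None = None, out_dir=None) -> ScenarioBundle:
    """Compose landscape, sites, and communities into one scenario bundle.

    Sites' ``plant_richness`` is synchronized with the simulated plant
    occurrence table so the richness covariate and the plant similarity
    response describe the same communities.  When ``out_dir`` is given
    all artifacts are written as plain-text files (ASCII raster, CSV
    tables, truth JSON).
    """
    cfg = cfg or ScenarioConfig()
    grid = simulate_landscape(cfg)
    sites = simulate_sites(cfg, grid)
    lls_lines = lc.extract_boundaries(grid, lc.SEMINATURAL_CLASS_SETS)
    if cfg.truth == "corridor":
        _, prop = _lls_proportion_grid(cfg, grid, lc.SEMINATURAL_CLASS_SETS)
        dist_km = _lcp_length_matrix(prop, sites, cfg.eps)
    else:
        dist_km = _euclid_matrix(sites)
    occ_bees, occ_plants, traits = simulate_communities(
        cfg, sites, grid, dist_km=dist_km, lls_lines=lls_lines
    )
    quality_latent = sites.attrs.get("quality_latent")
    sites = sites.copy()
    sites["plant_richness"] = richness(occ_plants).to_numpy(int)
    if quality_latent is not None:
        sites.attrs["quality_latent"] = quality_latent
    truth = {
        "truth": cfg.truth,
        "lambda_bumblebee_km": cfg.lambda_bumblebee_km,
        "lambda_solitary_km": cfg.lambda_solitary_km,
        "lambda_plants_km": cfg.lambda_plants_km,
        "p0": cfg.p0,
        "seed": cfg.seed,
        "mean_pair_distance_km": float(dist_km[np.triu_indices(len(sites), 1)].mean()),
    }
    bundle = ScenarioBundle(cfg, grid, sites, occ_bees, occ_plants, traits, truth)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
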