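"""End-to-end orchestration: rasters and tables in, model report out.

Stages: (1) derive the three LLS line maps (all seminatural, forest edge,
nonforest) and per-site landscape metrics; (2) rasterize and aggregate
edges into proportion grids and compute within-country corridor and
geographic distances; (3) curate bee occurrences and assemble the pair
similarity table; (4) fit the richness GLMs across radii with AICc radius
selection and residual diagnostics, run the distance-threshold
sensitivity scan, and compare distance-decay GLMMs against the null.
Every run records its configuration hash so reruns on identical inputs
are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from beecorridors import community, corridors, landcover as lc, raster_io, stats
from beecorridors.glmm import fit_crossed_glmm
from beecorridors.simulate import ScenarioBundle, read_occurrences


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    landcover_path: str | None = None
    sites_path: str | None = None
    bees_path: str | None = None
    plants_path: str | None = None
    traits_path: str | None = None
    out_dir: str | None = None
    radii_m: tuple = stats.DEFAULT_RADII
    aggregation_factor: int = 10
    eps: float = 1e-6
    family: str = "student_t"
    sensitivity_thresholds_km: tuple = stats.DEFAULT_THRESHOLDS
    sensitivity_min_pairs: int = 30
    max_distance_km: dict = field(default_factory=dict)  # per-country override
    seed: int = 0

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_inputs(cfg: RunConfig) -> ScenarioBundle:
    """Read the standard-format input files into an in-memory bundle."""
    grid = raster_io.read_landcover(cfg.landcover_path)
    sites = pd.read_csv(cfg.sites_path)
    traits = pd.read_csv(cfg.traits_path)
    occ_bees = read_occurrences(cfg.bees_path, site_ids=sites["id"])
    occ_plants = read_occurrences(cfg.plants_path, site_ids=sites["id"])
    from beecorridors.simulate import ScenarioConfig

    return ScenarioBundle(ScenarioConfig(), grid, sites, occ_bees, occ_plants, traits, {})


def validate_inputs(cfg: RunConfig, bundle: ScenarioBundle | None = None) -> list[str]:
    """Sanity checks on the assembled inputs; returns a list of issues
    (empty = pass).  Reports, never raises."""
    issues: list[str] = []
    try:
        bundle = bundle or load_inputs(cfg)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        return [f"could not load inputs: {exc}"]
    grid = bundle.landcover
    coords = bundle.sites[["x", "y"]].to_numpy(float)
    if not np.isfinite(coords).all():
        issues.append("site coordinates contain non-finite values")
    span = coords.max(axis=0) - coords.min(axis=0)
    if len(coords) > 1 and max(span) < 50:
        issues.append("site coordinate span < 50 m — are coordinates in meters?")
    for _, s in bundle.sites.iterrows():
        if not grid.contains(float(s["x"]), float(s["y"])):
            issues.append(f"site {s['id']!r} lies outside the land-cover raster")
    missing = sorted(
        set(bundle.occ_bees.columns)
        - set(bundle.traits["species"] if "species" in bundle.traits else bundle.traits.index)
    )
    if missing:
        issues.append(f"species missing trait rows: {missing}")
    if bundle.sites["id"].duplicated().any():
        issues.append("duplicate site ids")
    return issues


def run_pipeline(cfg: RunConfig, bundle: ScenarioBundle | None = None) -> dict:
    """Run the full analysis; returns the report dict (also written to
    ``out_dir`` together with the stage output tables when set)."""
    report: dict = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "stages": {},
        "warnings": [],
    }
    t_all = time.perf_counter()

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                report["stages"][name] = {"seconds": round(time.perf_counter() - self.t0, 3)}
                return False

        return _Ctx()

    with stage("load"):
        if bundle is None:
            bundle = load_inputs(cfg)
        grid, sites = bundle.landcover, bundle.sites

    with stage("landcover"):
        lines_all = lc.extract_boundaries(grid, lc.SEMINATURAL_CLASS_SETS, "all-seminatural")
        lines_forest = lc.extract_boundaries(grid, lc.FOREST_CLASSES, "forest")
        site_metrics = []
        for _, s in sites.iterrows():
            xy = (float(s["x"]), float(s["y"]))
            row = {"id": s["id"]}
            for r in cfg.radii_m:
                la = lc.length_within_radius(lines_all, xy, r)
                lf = lc.length_within_radius(lines_forest, xy, r)
                row[f"len_all_{r}"] = la
                row[f"len_forest_{r}"] = lf
                row[f"len_nonforest_{r}"] = max(la - lf, 0.0)
                row[f"grass_{r}"] = lc.grassland_proportion(grid, xy, r)
            site_metrics.append(row)
        site_metrics = pd.DataFrame(site_metrics)
        report["landcover"] = {
            "total_lls_length_km": lines_all.total_length / 1000.0,
            "forest_edge_length_km": lines_forest.total_length / 1000.0,
            "nonforest_length_km": lc.nonforest_length(lines_all, lines_forest) / 1000.0,
        }

    with stage("corridors"):
        grids = {}
        for name, lines in (("lls", lines_all), ("forest", lines_forest)):
            binary = lc.rasterize_lines(lines, grid.cell_size)
            grids[name] = lc.aggregate_proportion(binary, cfg.aggregation_factor)
        dists = corridors.pairwise_distances(sites, grids, eps=cfg.eps)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = dists["lcp_len_lls_km"] / dists["geo_km"]
        report["corridors"] = {
            "n_pairs": int(len(dists)),
            "lcp_geo_ratio_mean": float(ratio[np.isfinite(ratio)].mean()),
            "lcp_len_lls_km_mean": float(dists["lcp_len_lls_km"].mean()),
            "lcp_len_forest_km_mean": float(dists["lcp_len_forest_km"].mean()),
        }

    with stage("community"):
        bees = community.curate(bundle.occ_bees, bundle.traits)
        bee_richness = community.richness(bees)
        pairs = community.build_pair_table(
            sites, bees, bundle.occ_plants, community.pooled_traits(bundle.traits), dists
        )
        n_undef = pairs.attrs.get("n_undefined_similarity", 0)
        if n_undef:
            report["warnings"].append(f"{n_undef} pairs with undefined similarity dropped from fits")
        report["community"] = {
            "n_species": int(bees.shape[1]),
            "n_occurrences": int(bees.to_numpy().sum()),
            "richness_mean": float(bee_richness.mean()),
            "richness_range": [int(bee_richness.min()), int(bee_richness.max())],
            "sim_all_mean": float(pairs["sim_all"].mean()),
        }

    with stage("richness_models"):
        fits = {}
        for lls_type in ("all", "forest", "nonforest"):
            for r in cfg.radii_m:
                X = stats.richness_design(
                    sites, site_metrics[f"len_{lls_type}_{r}"], site_metrics[f"grass_{r}"]
                )
                fits[(lls_type, r)] = stats.fit_poisson_glm(
                    bee_richness.to_numpy(), X, label=f"{lls_type}@{r}m"
                )
        best, aicc_table = stats.select_radius(fits)
        null_X = stats.richness_design(
            sites, site_metrics[f"len_all_{cfg.radii_m[-1]}"],
            site_metrics[f"grass_{cfg.radii_m[-1]}"], include_lls=False,
        )
        null_fit = stats.fit_poisson_glm(bee_richness.to_numpy(), null_X, label="null")
        rich_report = {"best_radius_m": best, "aicc_null": null_fit.aicc,
                       "aicc_table": aicc_table.to_dict(), "per_type": {}}
        coords = sites[["x", "y"]].to_numpy(float)
        for lls_type, radius in best.items():
            f = fits[(lls_type, radius)]
            lrt, dfree, p = stats.lrt_drop1(f, "log_lls")
            i_obs, _, _, p_moran = stats.morans_i(f.resid_pearson, coords)
            ratio, flagged = stats.dispersion_check(f)
            if flagged:
                report["warnings"].append(
                    f"overdispersion flag for {lls_type} richness model (ratio {ratio:.2f})"
                )
            rich_report["per_type"][lls_type] = {
                "radius_m": radius,
                "aicc": f.aicc,
                "coef_log_lls": float(f.params["log_lls"]),
                "coef_plant_richness": float(f.params["plant_richness"]),
                "lrt_log_lls": {"stat": lrt, "df": dfree, "p": p},
                "morans_i": {"I": i_obs, "p": p_moran},
                "dispersion_ratio": ratio,
            }
        report["richness_models"] = rich_report

    with stage("sensitivity"):
        sens = stats.threshold_sensitivity(
            pairs, "sim_all", thresholds_km=cfg.sensitivity_thresholds_km,
            min_pairs=cfg.sensitivity_min_pairs,
        )
        for country, skipped in sens.skipped.items():
            if skipped:
                report["warnings"].append(
                    f"sensitivity: country {country} skipped thresholds {skipped} (<"
                    f"{cfg.sensitivity_min_pairs} pairs)"
                )
        report["sensitivity"] = {
            "chosen_km": sens.chosen_km,
            "delta_aicc": {c: {str(t): v for t, v in d.items()} for c, d in sens.delta_aicc.items()},
        }

    with stage("distance_models"):
        cut_tables = []
        for country, sub in pairs.groupby("country", sort=False):
            limit = cfg.max_distance_km.get(country, sens.chosen_km.get(country))
            if limit is not None:
                sub = sub[sub["geo_km"] <= limit]
            cut_tables.append(sub)
        pairs_cut = pd.concat(cut_tables, ignore_index=True)
        comp_tables = []
        for response in ("sim_all", "sim_solitary"):
            comp = stats.compare_distance_models(pairs_cut, response, family=cfg.family)
            comp_tables.append(comp)
        comparison = pd.concat(comp_tables, ignore_index=True)
        best_rows = comparison.loc[comparison.groupby(["country", "response"])["aicc"].idxmin()]
        report["distance_models"] = {
            "family": cfg.family,
            "n_pairs_used": int(len(pairs_cut)),
            "best_model": {
                f"{r.country}/{r.response}": {"model": r.model, "aicc": r.aicc,
                                              "delta_vs_geo": r.delta_aicc}
                for r in best_rows.itertuples()
            },
            "table": comparison.to_dict(orient="records"),
        }

    with stage("headline_fit"):
        headline = {}
        for response in ("sim_all", "sim_solitary"):
            for country, sub in pairs_cut.groupby("country", sort=False):
                f = fit_crossed_glmm(sub, response, "lcp_len_forest_km",
                                     family=cfg.family, compute_se=True)
                z = f.zvalues
                headline[f"{country}/{response}"] = {
                    "coef_lcp_len_forest_km": float(f.params["lcp_len_forest_km"]),
                    "z": float(z["lcp_len_forest_km"]) if z is not None else None,
                    "var_site_i": f.var_site_i,
                    "var_site_j": f.var_site_j,
                    "t_df": f.t_df,
                    "aicc": f.aicc,
                    "n": f.n,
                    "k": f.k,
                }
        report["headline_fit"] = headline

    report["seconds_total"] = round(time.perf_counter() - t_all, 3)

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=_jsonable))
        site_metrics.to_csv(out / "site_metrics.csv", index=False)
        dists.to_csv(out / "pair_distances.csv", index=False)
        pairs.to_csv(out / "pair_table.csv", index=False)
        aicc_table.to_csv(out / "aicc_radius_table.csv")
        comparison.to_csv(out / "distance_model_comparison.csv", index=False)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
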