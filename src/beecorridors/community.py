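"""Bee and plant community curation and compositional similarity.

Occurrence data are held as a wide sites x species count matrix
(:class:`pandas.DataFrame`, site ids in the index).  Curation drops
kleptoparasitic species (their distribution tracks hosts, not habitat) and
pools cryptic species complexes — e.g. the *Bombus sensu stricto*
subgenus, whose members cannot be separated morphologically — into one
morphospecies column.

Compositional similarity between two sites is 1 minus the binary
Bray–Curtis dissimilarity (A + B - 2J) / (A + B), i.e. 2J / (A + B), with
per-site presence richnesses A, B and J shared species.  The dummy-species
variant adds one artificial species present everywhere, keeping the index
defined for empty communities and damping zero inflation in sparse groups
such as solitary bees.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

TRAIT_COLUMNS = ("parasitic", "group", "cryptic_complex")


def _check_traits(occ: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    traits = traits.set_index("species") if "species" in traits.columns else traits
    missing = sorted(set(occ.columns) - set(traits.index))
    if missing:
        raise ValueError(f"species missing from trait table: {missing}")
    return traits


def curate(occ: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Drop parasitic species and pool cryptic complexes.

    Columns sharing a non-null ``cryptic_complex`` label are summed into a
    single morphospecies column named after the label.  The result's
    columns are sorted alphabetically; counts of retained species are
    conserved.
    """
    traits = _check_traits(occ, traits)
    keep = [s for s in occ.columns if not bool(traits.loc[s, "parasitic"])]
    out = occ[keep].copy()
    complexes = traits.loc[keep, "cryptic_complex"]
    for label, members in complexes.dropna().groupby(complexes.dropna()).groups.items():
        cols = [s for s in members]
        pooled = out[cols].sum(axis=1)
        out = out.drop(columns=cols)
        out[str(label)] = pooled
    return out[sorted(out.columns)]


def pooled_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Trait table augmented with one row per pooled morphospecies, so a
    curated occurrence table still has complete trait coverage."""
    t = traits.copy()
    if "species" not in t.columns:
        t = t.reset_index().rename(columns={"index": "species"})
    pooled = []
    for label, sub in t.dropna(subset=["cryptic_complex"]).groupby("cryptic_complex"):
        pooled.append(
            {"species": str(label), "parasitic": False,
             "group": sub["group"].iloc[0], "cryptic_complex": None}
        )
    if pooled:
        t = pd.concat([t, pd.DataFrame(pooled)], ignore_index=True)
    return t


def richness(occ: pd.DataFrame) -> pd.Series:
    """Number of species present (count > 0) at each site."""
    return (occ > 0).sum(axis=1)


def bray_curtis_similarity(
    occ: pd.DataFrame, i, j, dummy: bool = False
) -> float:
    """Binary Bray–Curtis similarity 2J / (A + B) between sites ``i``, ``j``.

    With ``dummy=True`` an artificial species present at both sites is
    added (A, B, J each + 1), so the index is defined even when both
    communities are empty.  Without it, an empty pair is undefined and
    ``nan`` is returned — never 0.
    """
    pi = occ.loc[i] > 0
    pj = occ.loc[j] > 0
    a = int(pi.sum())
    b = int(pj.sum())
    jshared = int((pi & pj).sum())
    if dummy:
        a, b, jshared = a + 1, b + 1, jshared + 1
    if a + b == 0:
        return float("nan")
    return 2.0 * jshared / (a + b)


def _similarity_table(occ: pd.DataFrame, pairs, dummy: bool) -> list[float]:
    pres = (occ > 0).to_numpy()
    pos = {s: k for k, s in enumerate(occ.index)}
    out = []
    for i, j in pairs:
        pi, pj = pres[pos[i]], pres[pos[j]]
        a, b = int(pi.sum()), int(pj.sum())
        jsh = int((pi & pj).sum())
        if dummy:
            a, b, jsh = a + 1, b + 1, jsh + 1
        out.append(2.0 * jsh / (a + b) if a + b > 0 else float("nan"))
    return out


def build_pair_table(
    sites: pd.DataFrame,
    occ_bees: pd.DataFrame,
    occ_plants: pd.DataFrame,
    traits: pd.DataFrame,
    dists: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the within-country pair table for distance-decay models.

    One row per unordered same-country site pair with bee similarity
    (``sim_all``), solitary-bee similarity computed on the solitary subset
    with the dummy species (``sim_solitary``), plant similarity
    (``sim_plants``), plant richness of both sites, and — when ``dists``
    from :func:`beecorridors.corridors.pairwise_distances` is given — the
    geographic and corridor distance columns merged in.

    ``occ_bees`` must already be curated; plant richness is the number of
    plant species recorded at the site in ``occ_plants``.
    """
    traits_idx = _check_traits(occ_bees, traits)
    for sid in sites["id"]:
        if sid not in occ_bees.index:
            raise ValueError(f"site {sid!r} missing from bee occurrence table")
        if sid not in occ_plants.index:
            raise ValueError(f"site {sid!r} missing from plant occurrence table")
    solitary_cols = [
        s for s in occ_bees.columns if str(traits_idx.loc[s, "group"]) == "solitary"
    ]
    plant_sr = richness(occ_plants)

    pairs, countries = [], []
    for country, group in sites.groupby("country", sort=False):
        ids = group["id"].to_list()
        for i, j in itertools.combinations(ids, 2):
            pairs.append((i, j))
            countries.append(country)

    table = pd.DataFrame(
        {
            "site_i": [p[0] for p in pairs],
            "site_j": [p[1] for p in pairs],
            "country": countries,
            "sim_all": _similarity_table(occ_bees, pairs, dummy=False),
            "sim_solitary": _similarity_table(occ_bees[solitary_cols], pairs, dummy=True),
            "sim_plants": _similarity_table(occ_plants, pairs, dummy=False),
            "plantSR_i": [int(plant_sr[p[0]]) for p in pairs],
            "plantSR_j": [int(plant_sr[p[1]]) for p in pairs],
        }
    )
    if dists is not None:
        table = table.merge(dists.drop(columns=["country"]), on=["site_i", "site_j"], how="left")
    n_undefined = int(table[["sim_all", "sim_plants"]].isna().any(axis=1).sum())
    table.attrs["n_undefined_similarity"] = n_undefined
    return table
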