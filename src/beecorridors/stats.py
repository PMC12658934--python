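"""Inferential layer: richness GLMs, spatial diagnostics, and
distance-decay model comparison.

Species richness at a site is modelled with a Poisson GLM (log link)

    richness ~ log(LLS length within radius) + plant richness
               + log(grassland proportion within radius) + country
               + Xcrds + Ycrds

fitted once per radius (250–1500 m) and LLS type (all seminatural, forest
edge, nonforest); the spatial scale is chosen by the lowest AICc.  Pearson
residuals are screened for spatial autocorrelation with Moran's I
(inverse-distance, row-standardized weights) and for overdispersion with
the Pearson chi-square / df ratio.  Term significance uses likelihood
ratio drop-one tests.

Pairwise similarity models (crossed-random-intercept GLMMs, see
:mod:`beecorridors.glmm`) are compared by AICc across candidate distance
measures — geographic, LCP length and LCP cost on each LLS map — against
a null model without any distance term; the distance-threshold
sensitivity analysis refits linear vs. quadratic distance models on
nested data subsets to find the range over which similarity declines
monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm

from beecorridors.glmm import GLMMFit, aicc, fit_crossed_glmm

DEFAULT_RADII = (250, 500, 750, 1000, 1250, 1500)
DEFAULT_THRESHOLDS = tuple(range(10, 110, 5))  # km; 10, 15, ..., 105
DISTANCE_MODELS = (
    "geo_km",
    "lcp_len_lls_km",
    "lcp_len_forest_km",
    "lcp_cost_lls",
    "lcp_cost_forest",
)

#: additive guards before log-transforming quantities that can be zero
LLS_LENGTH_LOG_OFFSET = 1.0  # meters
GRASSLAND_LOG_OFFSET = 1e-4  # proportion


@dataclass
class ModelFit:
    """A fitted (generalized) linear model with AICc bookkeeping."""

    label: str
    params: pd.Series
    llf: float
    k: int
    n: int
    fitted: np.ndarray = field(repr=False)
    resid_pearson: np.ndarray = field(repr=False)
    deviance: float = np.nan
    se: pd.Series | None = None
    y: np.ndarray | None = field(default=None, repr=False)
    X: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k, self.n)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    q, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
    aliased = [X.columns[i] for i in np.nonzero(diag <= tol)[0]]
    if aliased:
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def fit_poisson_glm(y, X: pd.DataFrame, label: str = "poisson") -> ModelFit:
    """Maximum-likelihood Poisson GLM with log link (IRLS).

    ``X`` must be a full-rank design with named columns (include the
    intercept explicitly).  Convergence is on the deviance at 1e-8 within
    100 iterations.
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("response must be nonnegative counts")
    _check_full_rank(X)
    model = sm.GLM(y, np.asarray(X, dtype=float), family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise RuntimeError("Poisson GLM did not converge in 100 iterations")
    k = X.shape[1]
    return ModelFit(
        label=label,
        params=pd.Series(res.params, index=list(X.columns)),
        llf=float(res.llf),
        k=k,
        n=len(y),
        fitted=np.asarray(res.fittedvalues),
        resid_pearson=np.asarray(res.resid_pearson),
        deviance=float(res.deviance),
        se=pd.Series(res.bse, index=list(X.columns)),
        y=y,
        X=X.copy(),
    )


def richness_design(
    sites: pd.DataFrame,
    lls_length_m,
    grassland_prop,
    include_lls: bool = True,
    interaction_with_country: bool = False,
) -> pd.DataFrame:
    """Design matrix for the richness GLM at one radius and LLS type.

    LLS lengths enter as ``log(length + 1 m)`` and grassland as
    ``log(prop + 1e-4)`` to guard against zeros; coordinates are centered
    and scaled by their standard deviation (affects coefficients only,
    not deviance or AICc differences).
    """
    countries = sorted(sites["country"].unique())
    X = pd.DataFrame({"Intercept": np.ones(len(sites))}, index=sites.index)
    log_lls = np.log(np.asarray(lls_length_m, dtype=float) + LLS_LENGTH_LOG_OFFSET)
    if include_lls:
        X["log_lls"] = log_lls
    X["plant_richness"] = sites["plant_richness"].to_numpy(float)
    X["log_grassland"] = np.log(np.asarray(grassland_prop, dtype=float) + GRASSLAND_LOG_OFFSET)
    for c in countries[1:]:
        X[f"country[{c}]"] = (sites["country"] == c).astype(float).to_numpy()
    for crd in ("x", "y"):
        v = sites[crd].to_numpy(float)
        sd = v.std() or 1.0
        X[f"{crd}crds"] = (v - v.mean()) / sd
    if interaction_with_country:
        if len(countries) != 2:
            raise ValueError("country interaction needs exactly 2 countries")
        X["log_lls:country"] = X["log_lls"] * X[f"country[{countries[1]}]"]
    return X


def select_radius(fits: dict) -> tuple[dict, pd.DataFrame]:
    """Best radius per LLS type by minimum AICc (ties -> smaller radius).

    ``fits`` maps ``(lls_type, radius)`` to a :class:`ModelFit`.  Returns
    the winning radius per type and the full AICc table (radius rows,
    type columns).
    """
    types = sorted({t for t, _ in fits}, key=str)
    radii = sorted({r for _, r in fits})
    table = pd.DataFrame(
        {t: [fits[(t, r)].aicc if (t, r) in fits else np.nan for r in radii] for t in types},
        index=pd.Index(radii, name="radius_m"),
    )
    best = {}
    for t in types:
        col = table[t].dropna()
        best[t] = int(col.index[np.argmin(col.to_numpy())])  # argmin: first = smallest radius
    return best, table


def lrt_drop1(full: ModelFit, term: str) -> tuple[float, int, float]:
    """Likelihood ratio test for dropping one term from a Poisson GLM.

    Refits without the named column (for an interaction, only the
    interaction column is removed).  Returns ``(LRT, df, p)`` with
    ``LRT = 2 (llf_full - llf_reduced)`` and a chi-square reference.
    """
    if full.X is None or term not in full.X.columns:
        raise ValueError(f"term {term!r} not in the fitted design")
    X_red = full.X.drop(columns=[term])
    reduced = fit_poisson_glm(full.y, X_red, label=f"{full.label} - {term}")
    stat = max(2.0 * (full.llf - reduced.llf), 0.0)
    df = full.k - reduced.k
    p = float(sstats.chi2.sf(stat, df))
    return float(stat), int(df), p


def morans_i(residuals, coords) -> tuple[float, float, float, float]:
    """Moran's I with inverse-distance, row-standardized weights.

    Returns ``(I, expected, sd, p)``; the expectation is -1/(n-1), the
    variance is the randomization (kurtosis-corrected) form, and the
    p-value a two-sided normal approximation.
    """
    z = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 points")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        raise ValueError("coincident points give infinite inverse-distance weights")
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)
    zc = z - z.mean()
    denom = float(zc @ zc)
    if denom == 0:
        raise ValueError("residuals have zero variance")
    s0 = w.sum()
    i_obs = n / s0 * float(zc @ w @ zc) / denom
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    kurt = n * (zc**4).sum() / denom**2
    var = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - kurt * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - 1.0 / (n - 1) ** 2
    sd = float(np.sqrt(var))
    p = float(2.0 * sstats.norm.sf(abs(i_obs - e_i) / sd))
    return float(i_obs), e_i, sd, p


def dispersion_check(fit: ModelFit, flag_threshold: float = 1.5) -> tuple[float, bool]:
    """Pearson chi-square / df overdispersion ratio for a Poisson fit.

    Returns ``(ratio, flagged)``; values near 1 indicate a well-specified
    Poisson model, ratios above ``flag_threshold`` suggest
    overdispersion.  A saturated fit (all residuals zero) gives 0.
    """
    ss = float((fit.resid_pearson**2).sum())
    dof = fit.n - fit.k
    if dof <= 0:
        return (0.0, False) if ss < 1e-12 else (float("inf"), True)
    ratio = ss / dof
    return ratio, bool(ratio > flag_threshold)


def compare_distance_models(
    pairs: pd.DataFrame,
    response: str,
    distance_columns: tuple[str, ...] = DISTANCE_MODELS,
    family: str = "gaussian",
    per_country: bool = True,
) -> pd.DataFrame:
    """AICc ranking of candidate distance measures against a null model.

    Fits one crossed-random-intercept GLMM per distance column plus the
    distance-free null, separately per country, and tabulates AICc and
    ``delta_aicc`` relative to the geographic-distance model (negative
    values mean the candidate beats plain geographic distance).
    """
    rows = []
    groups = pairs.groupby("country", sort=False) if per_country else [("all", pairs)]
    for country, sub in groups:
        fits: dict[str, GLMMFit] = {}
        fits["null"] = fit_crossed_glmm(sub, response, None, family=family, compute_se=False)
        for col in distance_columns:
            fits[col] = fit_crossed_glmm(sub, response, col, family=family, compute_se=False)
        ref = fits["geo_km"].aicc if "geo_km" in fits else min(f.aicc for f in fits.values())
        for name, f in fits.items():
            rows.append(
                {
                    "country": country,
                    "response": response,
                    "model": name,
                    "aicc": f.aicc,
                    "delta_aicc": f.aicc - ref,
                    "n": f.n,
                    "k": f.k,
                    "distance_coef": float(f.params.get(name, np.nan)) if name != "null" else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SensitivityResult:
    """Per-country linear-vs-quadratic distance sensitivity scan."""

    thresholds_km: tuple
    delta_aicc: dict  # country -> {threshold: AICc_linear - AICc_quadratic}
    chosen_km: dict  # country -> selected maximum distance
    skipped: dict  # country -> [thresholds with too few pairs]


def threshold_sensitivity(
    pairs: pd.DataFrame,
    response: str,
    thresholds_km: tuple = DEFAULT_THRESHOLDS,
    family: str = "gaussian",
    min_pairs: int = 30,
) -> SensitivityResult:
    """Find the distance range over which similarity declines monotonically.

    For each maximum-distance threshold the pairs below it are refit with
    an untransformed-distance model and a second-order polynomial model
    (both with crossed random intercepts); ``delta_aicc = AICc_linear -
    AICc_quadratic``, so negative values favor the untransformed model.
    The chosen threshold per country is the largest at which the linear
    model wins (delta < 0) or ties (|delta| < 2).  Thresholds with fewer
    than ``min_pairs`` pairs are skipped and logged.
    """
    thresholds_km = tuple(sorted(thresholds_km))
    delta: dict = {}
    chosen: dict = {}
    skipped: dict = {}
    work = pairs.copy()
    work["_d2"] = work["geo_km"] ** 2
    for country, sub in work.groupby("country", sort=False):
        delta[country] = {}
        skipped[country] = []
        for thr in thresholds_km:
            cut = sub[sub["geo_km"] <= thr]
            if len(cut) < min_pairs:
                skipped[country].append(thr)
                continue
            lin = fit_crossed_glmm(
                cut, response, "geo_km", family=family, extra_terms=(), compute_se=False
            )
            quad = fit_crossed_glmm(
                cut, response, "geo_km", family=family, extra_terms=("_d2",), compute_se=False
            )
            delta[country][thr] = lin.aicc - quad.aicc
        ok = [t for t, d in delta[country].items() if d < 0 or abs(d) < 2]
        chosen[country] = max(ok) if ok else None
    return SensitivityResult(thresholds_km, delta, chosen, skipped)
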