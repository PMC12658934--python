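"""Crossed-random-intercept mixed models for pairwise similarity data.

The distance-decay response is the compositional similarity of a *pair*
of sites, so every observation carries two grouping factors: the identity
of the first and of the second site.  The model is

    y_k = x_k' beta + u[site_i(k)] + v[site_j(k)] + e_k

with independent random intercepts u ~ N(0, s_u^2), v ~ N(0, s_v^2) and
either Gaussian or scaled Student-t residuals.  The two crossed intercepts
absorb site-specific differences in average similarity to all other sites.

Estimation is maximum likelihood.  For the Gaussian family the random
effects integrate out exactly: y ~ N(X beta, V) with
V = s_u^2 Zu Zu' + s_v^2 Zv Zv' + s_e^2 I, and beta and s_e^2 are profiled
out so the optimizer only searches the two variance ratios.  For the
Student-t family the marginal likelihood has no closed form and is
approximated by a Laplace integral over the random effects, with an inner
Fisher-scoring mode finder; in the limit of large t df the Laplace
approximation reproduces the exact Gaussian fit, which the tests exploit
as an oracle for the shared code path.

AICc bookkeeping counts fixed effects + 2 variance components + the
residual scale, plus the t df when estimated; this convention matters
when comparing families and is applied uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve, solve_triangular

_LOG2PI = np.log(2.0 * np.pi)
_T_DF_FLOOR = 2.01  # keep residual variance finite
_VAR_FLOOR_LOG = -30.0  # boundary fits: variance ratio e^-30 ~ 0


def aicc(llf: float, k: int, n: int) -> float:
    """AIC with small-sample correction: AIC + 2k(k+1)/(n-k-1)."""
    aic = -2.0 * llf + 2.0 * k
    if n > k + 1:
        return aic + 2.0 * k * (k + 1) / (n - k - 1)
    return float("inf")


@dataclass
class GLMMFit:
    """Fitted crossed-random-intercept mixed model."""

    label: str
    family: str
    params: pd.Series
    var_site_i: float
    var_site_j: float
    resid_scale: float
    t_df: float | None
    llf: float
    k: int
    n: int
    fitted: np.ndarray = field(repr=False)
    converged: bool = True
    boundary: bool = False
    se: pd.Series | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k, self.n)

    @property
    def zvalues(self) -> pd.Series | None:
        if self.se is None:
            return None
        return self.params / self.se


def _onehot(codes: np.ndarray, q: int) -> np.ndarray:
    Z = np.zeros((codes.size, q))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


class _GaussianWork:
    """Precomputed cross-products for the profiled Gaussian likelihood.

    With W = I + l_u Zu Zu' + l_v Zv Zv' = I + Z D Z', all W-weighted
    inner products reduce via the Woodbury identity to the q x q
    capacitance matrix M = I_q + D^(1/2) Z'Z D^(1/2), so each likelihood
    evaluation costs O(q^3 + q^2 p) regardless of the number of pairs.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, Zu: np.ndarray, Zv: np.ndarray):
        Z = np.hstack([Zu, Zv])
        self.qu, self.qv = Zu.shape[1], Zv.shape[1]
        self.n, self.p = X.shape
        self.G = Z.T @ Z
        self.U = Z.T @ X
        self.v = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.X = X
        self.y = y

    def solve(self, theta: np.ndarray):
        """(beta, s2, llf, cov_beta) at variance ratios exp(theta)."""
        lu, lv = np.exp(np.clip(theta, _VAR_FLOOR_LOG, 30.0))
        s = np.sqrt(np.concatenate([np.full(self.qu, lu), np.full(self.qv, lv)]))
        M = self.G * np.outer(s, s)
        M[np.diag_indices(len(s))] += 1.0
        L = np.linalg.cholesky(M)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        P = solve_triangular(L, s[:, None] * self.U, lower=True)
        r = solve_triangular(L, s * self.v, lower=True)
        A = self.XtX - P.T @ P  # X' W^-1 X
        b = self.Xty - P.T @ r  # X' W^-1 y
        c = self.yty - float(r @ r)  # y' W^-1 y
        beta = np.linalg.solve(A, b)
        rss = max(c - float(beta @ b), 1e-12 * max(self.yty, 1.0))
        s2 = max(rss / self.n, 1e-12)
        llf = -0.5 * (self.n * (np.log(2 * np.pi * s2) + 1.0) + logdet)
        cov_beta = s2 * np.linalg.inv(A)
        return beta, s2, llf, cov_beta


def _profiled_gaussian_nll(theta: np.ndarray, work: _GaussianWork) -> float:
    """-2 log profile likelihood at variance ratios exp(theta)."""
    try:
        return -2.0 * work.solve(theta)[2]
    except np.linalg.LinAlgError:
        return np.inf


def _t_rho(r: np.ndarray, nu: float) -> np.ndarray:
    """Negative log density of standard t (up to the scale term)."""
    c = (
        special.gammaln((nu + 1) / 2)
        - special.gammaln(nu / 2)
        - 0.5 * np.log(nu * np.pi)
    )
    return -(c - (nu + 1) / 2 * np.log1p(r**2 / nu))


def _t_psi(r: np.ndarray, nu: float) -> np.ndarray:
    return (nu + 1) * r / (nu + r**2)


def _t_neg_joint(b, X, y, Zu, Zv, beta, sig, nu, dinv, logdet_prior):
    """f(b) = -log p(y | b) - log p(b) for the Laplace integrand."""
    eta = X @ beta + Zu @ b[: Zu.shape[1]] + Zv @ b[Zu.shape[1] :]
    r = (y - eta) / sig
    return (
        float(_t_rho(r, nu).sum())
        + y.size * np.log(sig)
        + 0.5 * float(b * dinv @ b)
        + 0.5 * logdet_prior
        + 0.5 * b.size * _LOG2PI
    )


def _t_laplace_nll(phi, X, y, Zu, Zv, b_warm):
    """Negative Laplace log marginal likelihood for the t family.

    ``phi`` = (beta, log s_u^2, log s_v^2, log sigma, log(nu - floor)).
    ``b_warm`` is a 1-element list holding the previous random-effect
    mode, reused as the starting point of the inner optimization.
    """
    p = X.shape[1]
    qu, qv = Zu.shape[1], Zv.shape[1]
    q = qu + qv
    beta = phi[:p]
    log_su2, log_sv2 = np.clip(phi[p : p + 2], _VAR_FLOOR_LOG, 10.0)
    sig = float(np.exp(np.clip(phi[p + 2], -15.0, 10.0)))
    nu = _T_DF_FLOOR + float(np.exp(np.clip(phi[p + 3], -10.0, 12.0)))
    dinv = np.concatenate(
        [np.full(qu, np.exp(-log_su2)), np.full(qv, np.exp(-log_sv2))]
    )
    logdet_prior = qu * log_su2 + qv * log_sv2

    Z = np.hstack([Zu, Zv])
    b = b_warm[0].copy()
    f = _t_neg_joint(b, X, y, Zu, Zv, beta, sig, nu, dinv, logdet_prior)
    # Fisher scoring: expected weight of the t score is (nu+1)/(nu+3)
    w_fisher = (nu + 1) / (nu + 3) / sig**2
    H_fisher = w_fisher * (Z.T @ Z)
    H_fisher[np.diag_indices(q)] += dinv
    try:
        cf = cho_factor(H_fisher)
    except np.linalg.LinAlgError:
        return np.inf
    for _ in range(200):
        eta = X @ beta + Z @ b
        r = (y - eta) / sig
        grad = -Z.T @ _t_psi(r, nu) / sig + dinv * b
        if np.max(np.abs(grad)) < 1e-9:
            break
        step = cho_solve(cf, grad)
        t = 1.0
        for _ in range(40):
            b_new = b - t * step
            f_new = _t_neg_joint(b_new, X, y, Zu, Zv, beta, sig, nu, dinv, logdet_prior)
            if f_new <= f + 1e-12:
                break
            t *= 0.5
        if f - f_new < 1e-12 and np.max(np.abs(grad)) < 1e-6:
            b, f = b_new, f_new
            break
        b, f = b_new, f_new
    b_warm[0] = b

    # true Hessian at the mode for the Laplace determinant
    eta = X @ beta + Z @ b
    r = (y - eta) / sig
    w = (nu + 1) * (nu - r**2) / (nu + r**2) ** 2 / sig**2
    H = (Z * w[:, None]).T @ Z
    H[np.diag_indices(q)] += dinv
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:  # fall back on the PSD Fisher information
        sign, logdet_H = np.linalg.slogdet(H_fisher)
    # log L ~= -f(b_hat) + q/2 log 2pi - 1/2 log|H|
    return f + 0.5 * logdet_H - 0.5 * q * _LOG2PI


def fit_crossed_glmm(
    pairs: pd.DataFrame,
    response: str,
    distance: str | None,
    family: str = "gaussian",
    extra_terms: tuple[str, ...] = ("plantSR_i", "plantSR_j", "plantSR_i:plantSR_j", "sim_plants"),
    label: str | None = None,
    compute_se: bool = True,
    force_zero_variance: bool = False,
) -> GLMMFit:
    """Fit the pairwise distance-decay mixed model by maximum likelihood.

    Fixed effects are an intercept, the named ``distance`` column (omitted
    for the null model), and ``extra_terms``: plant richness at both
    sites, their interaction (``"a:b"`` syntax), and plant compositional
    similarity.  Random intercepts are crossed over ``site_i`` and
    ``site_j``.  Rows with missing response, distance, or covariates are
    dropped.

    Parameters
    ----------
    pairs
        Pair table from :func:`beecorridors.community.build_pair_table`
        merged with corridor distances.
    response
        Column with the similarity response (in [0, 1]).
    distance
        Distance column name, or ``None`` for the null model.
    family
        ``"gaussian"`` (exact marginal ML) or ``"student_t"`` (Laplace).

    Notes
    -----
    Internally all non-intercept columns are centered and scaled;
    coefficients are reported on the original scale.  Variance
    components may collapse to (numerical) zero — a boundary fit,
    flagged via ``boundary=True``.
    """
    if family not in ("gaussian", "student_t"):
        raise ValueError(f"unknown family {family!r}")
    term_names = ["Intercept"]
    if distance is not None:
        term_names.append(distance)
    term_names += [t for t in extra_terms]

    cols_needed = {response, "site_i", "site_j"}
    for t in term_names[1:]:
        cols_needed.update(t.split(":"))
    df = pairs.dropna(subset=[c for c in cols_needed if c in pairs.columns]).reset_index(drop=True)
    missing = cols_needed - set(df.columns)
    if missing:
        raise ValueError(f"pair table lacks columns: {sorted(missing)}")
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 pairs to fit")

    y = df[response].to_numpy(dtype=float)
    raw_cols = []
    for t in term_names:
        if t == "Intercept":
            raw_cols.append(np.ones(n))
        elif ":" in t:
            a, b = t.split(":")
            raw_cols.append(df[a].to_numpy(float) * df[b].to_numpy(float))
        else:
            raw_cols.append(df[t].to_numpy(float))
    X_raw = np.column_stack(raw_cols)
    # center/scale non-intercept columns for numerical stability
    mu = X_raw.mean(axis=0)
    sd = X_raw.std(axis=0)
    mu[0], sd[0] = 0.0, 1.0
    sd[sd == 0] = 1.0
    X = (X_raw - mu) / sd

    lev_i = pd.Categorical(df["site_i"])
    lev_j = pd.Categorical(df["site_j"])
    Zu = _onehot(lev_i.codes.astype(int), len(lev_i.categories))
    Zv = _onehot(lev_j.codes.astype(int), len(lev_j.categories))
    if len(lev_i.categories) < 2 or len(lev_j.categories) < 2:
        raise ValueError("need >= 2 distinct site_i and site_j levels")

    p = X.shape[1]
    label = label or (distance if distance is not None else "null")

    # --- Gaussian fit (also the starting point for the t family) -------
    work = _GaussianWork(X, y, Zu, Zv)
    if force_zero_variance:
        theta = np.array([_VAR_FLOOR_LOG, _VAR_FLOOR_LOG])
        converged = True
    else:
        # scan a coarse grid of variance-ratio starts, polish the best one
        starts = [(-1.0, -1.0), (-4.0, -4.0), (-8.0, -8.0), (1.0, 1.0)]
        vals = [_profiled_gaussian_nll(np.asarray(s), work) for s in starts]
        best = optimize.minimize(
            _profiled_gaussian_nll, np.asarray(starts[int(np.argmin(vals))]),
            args=(work,), method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 400},
        )
        theta = best.x
        converged = bool(best.success)
    beta_s, s2, llf, cov_beta_s = work.solve(theta)
    lu, lv = np.exp(np.clip(theta, _VAR_FLOOR_LOG, 30.0))
    su2, sv2 = lu * s2, lv * s2
    fitted = X @ beta_s
    boundary = bool(np.any(theta < _VAR_FLOOR_LOG / 2))

    if family == "gaussian":
        k = p + 3  # fixed effects + 2 variances + residual scale
        beta = beta_s / sd
        beta[0] -= float((beta_s[1:] * mu[1:] / sd[1:]).sum())
        se = np.sqrt(np.diag(cov_beta_s)) / sd
        fit = GLMMFit(
            label=label, family=family,
            params=pd.Series(beta, index=term_names),
            var_site_i=su2, var_site_j=sv2, resid_scale=float(np.sqrt(s2)),
            t_df=None, llf=float(llf), k=k, n=n, fitted=fitted,
            converged=converged, boundary=boundary,
            se=pd.Series(se, index=term_names) if compute_se else None,
        )
        return fit

    # --- Student-t via Laplace ------------------------------------------
    nu0 = 5.0
    sig0 = np.sqrt(s2 * (nu0 - 2.0) / nu0)
    phi0 = np.concatenate(
        [
            beta_s,
            [max(np.log(su2), _VAR_FLOOR_LOG), max(np.log(sv2), _VAR_FLOOR_LOG)],
            [np.log(max(sig0, 1e-8))],
            [np.log(nu0 - _T_DF_FLOOR)],
        ]
    )
    b_warm = [np.zeros(Zu.shape[1] + Zv.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            _t_laplace_nll, phi0, args=(X, y, Zu, Zv, b_warm),
            method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7},
        )
    phi = res.x
    nll = _t_laplace_nll(phi, X, y, Zu, Zv, b_warm)
    if not np.isfinite(nll):
        raise RuntimeError(f"t-family GLMM did not converge (status {res.status})")
    beta_s = phi[:p]
    su2, sv2 = np.exp(np.clip(phi[p : p + 2], _VAR_FLOOR_LOG, 10.0))
    sig = float(np.exp(phi[p + 2]))
    nu = _T_DF_FLOOR + float(np.exp(phi[p + 3]))
    beta = beta_s / sd
    beta[0] -= float((beta_s[1:] * mu[1:] / sd[1:]).sum())

    se = None
    if compute_se:
        se = _t_beta_se(phi, X, y, Zu, Zv, b_warm, p) / sd
    k = p + 4  # fixed + 2 variances + scale + t df
    return GLMMFit(
        label=label, family=family,
        params=pd.Series(beta, index=term_names),
        var_site_i=float(su2), var_site_j=float(sv2), resid_scale=sig,
        t_df=nu, llf=float(-nll), k=k, n=n, fitted=X @ beta_s,
        converged=bool(res.success), boundary=bool(np.any(phi[p : p + 2] < _VAR_FLOOR_LOG / 2)),
        se=pd.Series(se, index=term_names) if se is not None else None,
    )


def _t_beta_se(phi, X, y, Zu, Zv, b_warm, p):
    """Observed-information SEs for the fixed effects of the t fit.

    Finite-difference Hessian of the Laplace negative log likelihood over
    the beta block only (variance parameters held at the ML estimates).
    """
    def nll_beta(beta):
        ph = phi.copy()
        ph[:p] = beta
        return _t_laplace_nll(ph, X, y, Zu, Zv, [b_warm[0].copy()])

    beta = phi[:p].copy()
    h = 1e-4 * np.maximum(np.abs(beta), 1.0)
    H = np.zeros((p, p))
    f0 = nll_beta(beta)
    for a in range(p):
        for b in range(a, p):
            ea = np.eye(p)[a] * h[a]
            eb = np.eye(p)[b] * h[b]
            fpp = nll_beta(beta + ea + eb)
            fpm = nll_beta(beta + ea - eb)
            fmp = nll_beta(beta - ea + eb)
            fmm = nll_beta(beta - ea - eb)
            H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h[a] * h[b])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se
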