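"""Poisson richness GLMs, diagnostics, and model-comparison machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats as sstats

from beecorridors.glmm import aicc
from beecorridors.stats import (
    DEFAULT_THRESHOLDS,
    ModelFit,
    compare_distance_models,
    dispersion_check,
    fit_poisson_glm,
    lrt_drop1,
    morans_i,
    richness_design,
    select_radius,
    threshold_sensitivity,
)


def design(**cols):
    return pd.DataFrame(cols)


class TestPoissonGLM:
    def test_intercept_only_matches_closed_form(self):
        y = np.array([1, 2, 3])
        fit = fit_poisson_glm(y, design(Intercept=np.ones(3)))
        assert fit.params["Intercept"] == pytest.approx(np.log(2.0))
        mu = 2.0
        llf = float((y * np.log(mu) - mu - special.gammaln(y + 1)).sum())
        assert fit.llf == pytest.approx(llf)

    def test_binary_covariate_recovers_group_log_means(self):
        y = np.array([2, 4, 2, 4, 8, 10, 8, 10])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        fit = fit_poisson_glm(y, design(Intercept=np.ones(8), g=g))
        assert fit.params["Intercept"] == pytest.approx(np.log(3.0))
        assert fit.params["g"] == pytest.approx(np.log(9.0 / 3.0))

    def test_score_vanishes_at_optimum(self, rng):
        n = 80
        X = design(
            Intercept=np.ones(n),
            x1=rng.normal(size=n),
            x2=rng.normal(size=n),
        )
        eta = 1.0 + 0.3 * X["x1"] - 0.2 * X["x2"]
        y = rng.poisson(np.exp(eta))
        fit = fit_poisson_glm(y, X)
        score = X.to_numpy().T @ (y - fit.fitted)
        assert np.abs(score).max() < 1e-6

    def test_fitted_sum_equals_response_sum(self, rng):
        n = 50
        X = design(Intercept=np.ones(n), x=rng.normal(size=n))
        y = rng.poisson(3.0, n)
        fit = fit_poisson_glm(y, X)
        assert fit.fitted.sum() == pytest.approx(y.sum())

    def test_rank_deficient_names_column(self):
        X = design(Intercept=np.ones(5), dup=np.ones(5))
        with pytest.raises(ValueError, match="dup"):
            fit_poisson_glm(np.arange(5), X)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_poisson_glm(np.array([-1, 2]), design(Intercept=np.ones(2)))


class TestAICcSelection:
    def make_fit(self, label, llf, k=7, n=40):
        return ModelFit(label, pd.Series(dtype=float), llf, k, n,
                        np.zeros(n), np.zeros(n))

    def test_picks_minimum(self):
        fits = {
            ("all", 250): self.make_fit("a", -180.0),
            ("all", 500): self.make_fit("b", -170.0),
            ("all", 750): self.make_fit("c", -175.0),
        }
        best, table = select_radius(fits)
        assert best["all"] == 500
        assert table.shape == (3, 1)

    def test_tie_prefers_smaller_radius(self):
        fits = {
            ("forest", 500): self.make_fit("a", -170.0),
            ("forest", 1000): self.make_fit("b", -170.0),
        }
        best, _ = select_radius(fits)
        assert best["forest"] == 500

    def test_aicc_formula(self):
        f = self.make_fit("x", -100.0, k=5, n=30)
        assert f.aic == pytest.approx(210.0)
        assert f.aicc == pytest.approx(210.0 + 2 * 5 * 6 / (30 - 5 - 1))
        # correction vanishes as n grows
        assert aicc(-100.0, 5, 10**6) == pytest.approx(210.0, abs=1e-3)

    def test_radius_selection_recovers_generating_scale(self, rng):
        # richness responds to the 1000 m metric; the 1000 m model should
        # (usually) win the AICc comparison across the radius grid
        radii = (250, 500, 750, 1000, 1250, 1500)
        hits = 0
        n = 68
        n_rep = 20
        for _ in range(n_rep):
            base = rng.normal(size=n)
            metrics = {
                r: 0.93 ** abs(k - 3) * base + 0.35 * rng.normal(size=n)
                for k, r in enumerate(radii)
            }
            y = rng.poisson(np.exp(1.8 + 0.5 * metrics[1000]))
            fits = {}
            for r in radii:
                X = design(Intercept=np.ones(n), m=metrics[r])
                fits[("all", r)] = fit_poisson_glm(y, X)
            best, _ = select_radius(fits)
            if abs(radii.index(best["all"]) - radii.index(1000)) <= 1:
                hits += 1
        assert hits >= int(0.8 * n_rep)


class TestLRT:
    def test_equals_deviance_difference(self, rng):
        n = 60
        X = design(Intercept=np.ones(n), x=rng.normal(size=n), z=rng.normal(size=n))
        y = rng.poisson(np.exp(1.0 + 0.4 * X["x"]))
        full = fit_poisson_glm(y, X)
        stat, df, p = lrt_drop1(full, "z")
        reduced = fit_poisson_glm(y, X.drop(columns=["z"]))
        assert stat == pytest.approx(reduced.deviance - full.deviance, abs=1e-8)
        assert df == 1
        assert 0 <= p <= 1

    def test_unknown_term_rejected(self, rng):
        X = design(Intercept=np.ones(10), x=rng.normal(size=10))
        full = fit_poisson_glm(rng.poisson(2, 10), X)
        with pytest.raises(ValueError, match="nope"):
            lrt_drop1(full, "nope")


class TestMoransI:
    def test_matches_ape_reference(self):
        # fixture regenerated deterministically; expected values computed
        # once with ape::Moran.I (row-normalized 1/d weights) and frozen
        r = np.random.default_rng(7)
        pts = r.uniform(0, 100, size=(8, 2))
        z = r.normal(0, 1, 8)
        i_obs, e_i, sd, p = morans_i(z, pts)
        assert i_obs == pytest.approx(-0.16824560, abs=1e-8)
        assert e_i == pytest.approx(-0.14285714, abs=1e-8)
        assert sd == pytest.approx(0.07792044, abs=1e-8)
        assert p == pytest.approx(0.74455653, abs=1e-7)

    def test_three_point_hand_computation(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        z = np.array([1.0, -0.5, -0.5])
        i_obs, e_i, _, _ = morans_i(z, pts)
        # equilateral: row-normalized weights all 1/2; I = n/S0 * num/den
        zc = z - z.mean()
        w = np.full((3, 3), 0.5)
        np.fill_diagonal(w, 0.0)
        expect = 3 / w.sum() * (zc @ w @ zc) / (zc @ zc)
        assert i_obs == pytest.approx(expect)
        assert e_i == pytest.approx(-0.5)

    def test_random_residuals_center_on_expectation(self, rng):
        n = 25
        pts = rng.uniform(0, 100, size=(n, 2))
        vals = [morans_i(rng.normal(size=n), pts)[0] for _ in range(400)]
        assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=0.01)

    def test_constant_residuals_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(np.ones(4), np.arange(8).reshape(4, 2))

    def test_coincident_points_error(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="coincident"):
            morans_i(np.array([1.0, 2.0, 3.0]), pts)


class TestDispersion:
    def test_well_specified_poisson_near_one(self, rng):
        n = 200
        X = design(Intercept=np.ones(n), x=rng.normal(size=n))
        y = rng.poisson(np.exp(1.5 + 0.3 * X["x"]))
        ratio, flagged = dispersion_check(fit_poisson_glm(y, X))
        assert ratio == pytest.approx(1.0, abs=0.25)
        assert not flagged

    def test_negative_binomial_overdispersion_flagged(self, rng):
        n = 200
        X = design(Intercept=np.ones(n))
        mu = 5.0
        lam = rng.gamma(shape=1.0, scale=mu)  # strong extra-Poisson noise
        y = rng.poisson(rng.gamma(shape=1.5, scale=mu / 1.5, size=n))
        ratio, flagged = dispersion_check(fit_poisson_glm(y, X))
        assert ratio > 1.5
        assert flagged

    def test_saturated_fit_zero(self):
        y = np.array([3, 5])
        X = design(Intercept=np.ones(2), x=np.array([0.0, 1.0]))
        fit = fit_poisson_glm(y, X)
        ratio, flagged = dispersion_check(fit)
        assert ratio == 0.0
        assert not flagged


class TestDistanceModelComparison:
    def test_duplicate_distance_columns_identical_aicc(self):
        from tests_helpers import decay_pairs

        df = decay_pairs(seed=3, n_sites=15)
        df["geo_km_copy"] = df["geo_km"]
        comp = compare_distance_models(
            df.assign(country="X"), "sim",
            distance_columns=("geo_km", "geo_km_copy"), family="gaussian",
        )
        piv = comp.set_index("model")["aicc"]
        assert piv["geo_km"] == pytest.approx(piv["geo_km_copy"], abs=1e-4)

    def test_threshold_grid_is_complete(self):
        assert DEFAULT_THRESHOLDS == tuple(range(10, 110, 5))
        assert len(DEFAULT_THRESHOLDS) == 20


class TestThresholdSensitivity:
    def test_monotone_decay_keeps_everything(self):
        from tests_helpers import decay_pairs

        df = decay_pairs(seed=1, n_sites=25).assign(country="X")
        res = threshold_sensitivity(df, "sim", family="gaussian")
        assert res.chosen_km["X"] == 105

    def test_too_few_pairs_skipped(self):
        from tests_helpers import decay_pairs

        df = decay_pairs(seed=2, n_sites=10).assign(country="X")
        df = df[df["geo_km"] > 30]
        res = threshold_sensitivity(df, "sim", family="gaussian", min_pairs=10)
        assert 10 in res.skipped["X"]
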