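"""Distributional-regression core: FP designs, ML fitting, selection,
centiles and diagnostics."""

import numpy as np
import pytest

from eegnorm.families import get_family
from eegnorm.gamlss import (FitError, build_fp_design, centile_curves,
                            filliben_correlation, fit_gamlss, fp_basis,
                            model_diagnostics, select_covariates,
                            select_distribution, select_fp_powers)


class TestFPDesign:
    def test_power_one_is_scaled_age(self):
        ages = np.array([40.0, 60.0, 80.0])
        X, names = build_fp_design(ages, (1.0,))
        assert names == ["intercept", "age^1"]
        assert np.allclose(X[:, 1], ages / 100.0)

    def test_power_zero_is_log(self):
        ages = np.array([40.0, 60.0, 80.0])
        X, names = build_fp_design(ages, (0.0,))
        assert names == ["intercept", "log(age)"]
        assert np.allclose(X[:, 1], np.log(ages / 100.0))

    def test_repeated_power_rule(self):
        # FP convention: a repeated power p contributes a^p and a^p*log(a)
        ages = np.linspace(41, 90, 7)
        a = ages / 100.0
        X, names = build_fp_design(ages, (2.0, 2.0))
        assert np.allclose(X[:, 1], a ** 2)
        assert np.allclose(X[:, 2], a ** 2 * np.log(a))

    def test_rank_deficiency_names_columns(self):
        ages = np.full(10, 65.0)  # constant age -> collinear with intercept
        with pytest.raises(ValueError, match="rank-deficient"):
            build_fp_design(ages, (1.0,))

    def test_fp_basis_negative_powers_finite(self):
        B = fp_basis(np.linspace(40, 92, 20), (-2.0, -0.5, 3.0))
        assert np.all(np.isfinite(B))


class TestFit:
    def test_normal_intercept_only_matches_closed_form(self, rng):
        y = rng.normal(0.5, 0.1, 400)
        fit = fit_gamlss(y, {}, "NO", n_restarts=0)
        assert fit.converged
        assert fit.coef["mu"][0] == pytest.approx(y.mean(), abs=1e-6)
        assert np.exp(fit.coef["sigma"][0]) == pytest.approx(
            y.std(), abs=1e-6)  # ML sd, divisor n

    def test_bic_formula(self, rng):
        y = rng.normal(0.0, 1.0, 120)
        fit = fit_gamlss(y, {}, "NO", n_restarts=0)
        k = len(fit.coef["mu"]) + len(fit.coef["sigma"])
        assert fit.bic == pytest.approx(-2 * fit.loglik + k * np.log(120),
                                        abs=1e-10)

    def test_loglik_not_below_initialization(self, rng):
        fam = get_family("JSU")
        y = rng.normal(0.3, 0.05, 200) + 0.02 * rng.standard_normal(200) ** 2
        fit = fit_gamlss(y, {}, fam, n_restarts=1)
        init = fam.initial_params(y)
        ll0 = float(np.sum(fam.logpdf(y, init)))
        assert fit.loglik >= ll0 - 1e-6

    def test_too_few_observations_raise(self):
        with pytest.raises(FitError):
            fit_gamlss(np.array([1.0, 2.0]), {}, "BCT")

    def test_response_outside_support_raises(self, rng):
        y = rng.normal(0, 1, 50)  # negative values, positive-support family
        with pytest.raises(FitError):
            fit_gamlss(y, {}, "BCCG")

    def test_bct_median_curve_recovery(self):
        """Simulated BCT data with a linear-FP median trend: the fitted
        median curve should track the generating median within 5%."""
        fam = get_family("BCT")
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            ages = rng.uniform(40, 92, 400)
            mu = 0.6 - 0.25 * ages / 100.0
            params = [mu, 0.1, 0.5, 10.0]
            u = rng.uniform(0.001, 0.999, 400)
            y = fam.ppf(u, [np.asarray(p, float) for p in params])
            X, names = build_fp_design(ages, (1.0,))
            fit = fit_gamlss(y, {"mu": X}, fam, n_restarts=1, seed=seed,
                             powers=(1.0,), column_names={"mu": names})
            if not fit.converged:
                continue
            grid = np.linspace(42, 90, 25)
            c = centile_curves(fit, grid, percentiles=(50,))
            truth = fam.ppf(np.full(25, 0.5),
                            [0.6 - 0.25 * grid / 100.0, 0.1, 0.5, 10.0])
            rel = np.median(np.abs(c["p50"] - truth) / truth)
            if rel < 0.05:
                hits += 1
        assert hits >= n_seeds - 1


class TestSelection:
    def test_single_candidate_returned(self, rng):
        y = rng.normal(0.5, 0.1, 100)
        fit = select_distribution(y, {}, ["JSU"], n_restarts=0)
        assert fit.family == "JSU"

    def test_selection_order_invariance(self, rng):
        y = np.abs(rng.normal(0.5, 0.1, 150)) + 0.01
        a = select_distribution(y, {}, ["NO", "BCCG", "JSU"], n_restarts=0)
        b = select_distribution(y, {}, ["JSU", "NO", "BCCG"], n_restarts=0)
        assert a.family == b.family
        assert a.bic == pytest.approx(b.bic, abs=1e-8)

    def test_gaussian_data_prefers_normal(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            y = np.abs(rng.normal(0.5, 0.05, 400)) + 1e-6
            fit = select_distribution(y, {}, ["NO", "BCCG", "BCT", "JSU"],
                                      n_restarts=0, seed=seed)
            wins += fit.family == "NO"
        assert wins >= 8

    def test_skewed_data_prefers_skew_family(self):
        fam = get_family("BCCG")
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            u = rng.uniform(0.001, 0.999, 400)
            y = fam.ppf(u, [0.5, 0.35, -1.5])  # strongly right-skewed
            fit = select_distribution(y, {}, ["NO", "BCCG", "BCT", "JSU"],
                                      n_restarts=0, seed=seed)
            wins += fit.family != "NO"
        assert wins >= 8

    def test_fp_power_search_finds_linear_trend(self, rng):
        ages = rng.uniform(40, 92, 400)
        y = 0.2 + 0.3 * ages / 100.0 + rng.normal(0, 0.03, 400)
        pw = select_fp_powers(y, ages, max_degree=1)
        assert len(pw) == 1  # FP1 suffices for a linear trend

    def test_covariate_kept_iff_it_lowers_bic(self):
        kept_strong, kept_none = 0, 0
        for seed in range(8):
            rng = np.random.default_rng(400 + seed)
            n = 300
            ages = rng.uniform(40, 92, n)
            sex = (rng.random(n) < 0.5).astype(float)
            base = 0.5 - 0.1 * ages / 100.0
            y_strong = base + 0.1 * sex + rng.normal(0, 0.1, n)  # 1 sigma
            y_none = base + rng.normal(0, 0.1, n)
            f1 = select_covariates(y_strong, ages, (1.0,), {"sex": sex},
                                   seed=seed, n_restarts=0)
            f0 = select_covariates(y_none, ages, (1.0,), {"sex": sex},
                                   seed=seed, n_restarts=0)
            kept_strong += "sex" in f1.covariates
            kept_none += "sex" in f0.covariates
        assert kept_strong >= 7
        assert kept_none <= 2

    def test_no_optional_covariates_returns_base(self, rng):
        ages = rng.uniform(40, 92, 150)
        y = 0.5 - 0.1 * ages / 100.0 + rng.normal(0, 0.05, 150)
        fit = select_covariates(y, ages, (1.0,), {}, n_restarts=0)
        assert fit.covariates == ()


class TestCentiles:
    def test_normal_quantile_identity(self, rng):
        ages = rng.uniform(40, 92, 300)
        y = 0.5 - 0.2 * ages / 100.0 + rng.normal(0, 0.05, 300)
        X, names = build_fp_design(ages, (1.0,))
        fit = fit_gamlss(y, {"mu": X}, "NO", n_restarts=0, powers=(1.0,),
                         column_names={"mu": names})
        grid = np.linspace(45, 85, 9)
        c = centile_curves(fit, grid)
        mu = fit.coef["mu"][0] + fit.coef["mu"][1] * grid / 100.0
        sigma = np.exp(fit.coef["sigma"][0])
        assert np.allclose(c["p50"], mu, atol=1e-6)
        assert np.allclose(c["p5"], mu - 1.6449 * sigma, atol=1e-4)

    def test_curves_strictly_ordered(self, rng):
        y = np.abs(rng.normal(0.5, 0.15, 300)) + 0.01
        fit = fit_gamlss(y, {}, "BCCG", n_restarts=1)
        c = centile_curves(fit, np.linspace(40, 92, 30))
        assert np.all(c["p5"] < c["p50"])
        assert np.all(c["p50"] < c["p95"])

    def test_extrapolation_flagged(self, rng):
        y = rng.normal(0.5, 0.1, 100)
        fit = fit_gamlss(y, {}, "NO", n_restarts=0)
        c = centile_curves(fit, np.array([30.0, 65.0, 95.0]),
                           age_range=(40, 92))
        assert list(c["extrapolated"]) == [True, False, True]


class TestDiagnostics:
    def test_training_residual_mean_centered(self, rng):
        y = rng.normal(0.5, 0.1, 400)
        fit = fit_gamlss(y, {}, "NO", n_restarts=0)
        d = model_diagnostics(fit, y, {})
        # ML centering: residual mean vanishes on the training data
        assert abs(d["mean"]) < 1e-6
        assert d["variance"] == pytest.approx(1.0, abs=0.05)

    def test_well_specified_calibration(self):
        good = 0
        for seed in range(8):
            rng = np.random.default_rng(500 + seed)
            ages = rng.uniform(40, 92, 400)
            from eegnorm.gamlss import build_fp_design
            y = 0.5 - 0.2 * ages / 100 + rng.normal(0, 0.05, 400)
            X, names = build_fp_design(ages, (1.0,))
            fit = fit_gamlss(y, {"mu": X}, "NO", n_restarts=0,
                             powers=(1.0,), column_names={"mu": names})
            d = model_diagnostics(fit, y, {"mu": X})
            if (-0.15 < d["mean"] < 0.15 and 0.8 < d["variance"] < 1.2
                    and d["filliben"] > 0.99):
                good += 1
        assert good >= 7

    def test_misspecified_fit_has_lower_filliben(self, rng):
        fam = get_family("BCCG")
        u = rng.uniform(0.001, 0.999, 400)
        y = fam.ppf(u, [0.5, 0.4, -1.8])  # strong skew
        bad = fit_gamlss(y, {}, "NO", n_restarts=0)
        good = fit_gamlss(y, {}, "BCCG", n_restarts=1)
        db = model_diagnostics(bad, y, {})
        dg = model_diagnostics(good, y, {})
        assert db["filliben"] < dg["filliben"]

    def test_filliben_of_normal_sample_near_one(self, rng):
        assert filliben_correlation(rng.standard_normal(500)) > 0.995
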