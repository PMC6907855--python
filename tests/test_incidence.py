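"""Mass-action incidence regression: fits, AIC, intervals, diagnostics,
model comparison and the multi-species extension."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from vipermass import incidence, synth
from tests.conftest import make_noisy_table


class TestFitModel:
    def test_noiseless_recovery_exact(self, district_table):
        fit = incidence.fit_model(district_table, 1)
        assert fit.params["alpha"] == pytest.approx(0.47, abs=1e-8)
        assert fit.params["theta"] == pytest.approx(1e-3, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("model_id", [1, 2, 3, 4, 5])
    def test_matches_independent_minimizer(self, model_id):
        """Coefficients agree with a derivative-free RSS minimizer (n=15)."""
        rng = np.random.default_rng(model_id)
        n = 15
        table = pd.DataFrame({
            "district_id": np.arange(n),
            "rural_pop": rng.lognormal(7, 1, n).round(),
            "F": rng.uniform(0, 0.3, n),
            "observed_incidence": rng.uniform(0, 10, n),
        })
        fit = incidence.fit_model(table, model_id)
        X, intercept = incidence.design_matrix(table, model_id)
        y = table["observed_incidence"].to_numpy()
        if intercept:
            X = np.column_stack([np.ones(n), X])

        def rss(beta):
            r = y - X @ beta
            return r @ r

        res = optimize.minimize(rss, np.zeros(X.shape[1]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 20000})
        assert np.allclose(fit.params.to_numpy(), res.x, atol=1e-6)

    def test_intercept_residuals_sum_to_zero(self, district_table):
        for mid in (1, 3, 4, 5):
            fit = incidence.fit_model(district_table, mid)
            assert abs(fit.residuals.sum()) < 1e-8 * max(1, fit.observed.sum())

    def test_theta_ci_coverage_at_zero_truth(self):
        """99% CI for theta covers a zero truth ~99% of the time."""
        covered = 0
        n_rep = 500
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 50
            S = rng.lognormal(8, 1, n).round()
            F = rng.uniform(0, 0.3, n)
            y = 2.0 + rng.normal(0, 1.0, n)  # theta = 0 truth
            table = pd.DataFrame({"district_id": np.arange(n),
                                  "rural_pop": S, "F": F,
                                  "observed_incidence": np.maximum(y, 0)})
            fit = incidence.fit_model(table, 1)
            ci = incidence.confint_params(fit, level=0.99)
            if ci.loc["theta", "low"] <= 0 <= ci.loc["theta", "high"]:
                covered += 1
        # Binomial(500, 0.99) three-sigma band.
        assert covered >= 488

    def test_rank_deficiency_reported(self):
        table = pd.DataFrame({
            "district_id": range(10),
            "rural_pop": np.ones(10),
            "F": np.ones(10),
            "observed_incidence": np.arange(10.0),
        })
        with pytest.raises(ValueError, match="constant|rank"):
            incidence.fit_model(table, 1)

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame({
            "district_id": [0, 1, 2],
            "rural_pop": [1.0, 2.0, 3.0],
            "F": [0.1, 0.2, 0.3],
            "observed_incidence": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValueError, match="at least"):
            incidence.fit_model(table, 5)


class TestAIC:
    def test_formula_on_hand_fixture(self):
        """Five-point fixture evaluated directly against the formula."""
        rss, n, k = 2.5, 5, 2
        expect = n * np.log(2 * np.pi * rss / n) + n + 2 * (k + 1)
        assert incidence.gaussian_aic(rss, n, k) == pytest.approx(expect,
                                                                  abs=1e-10)

    def test_extra_parameter_costs_two(self):
        a1 = incidence.gaussian_aic(3.0, 50, 2)
        a2 = incidence.gaussian_aic(3.0, 50, 3)
        assert a2 - a1 == pytest.approx(2.0)

    def test_zero_rss_guard(self):
        with pytest.warns(UserWarning, match="RSS"):
            assert incidence.gaussian_aic(0.0, 10, 2) == -np.inf

    def test_ranking_invariant_to_predictor_rescaling(self):
        table = make_noisy_table(3, n=60)
        base = incidence.compare_models(table).table["aic"].to_numpy()
        scaled = table.copy()
        scaled["F"] = scaled["F"] * 1000
        again = incidence.compare_models(scaled).table["aic"].to_numpy()
        assert np.allclose(base, again, atol=1e-8)


class TestIntervals:
    def test_zero_noise_zero_width(self, district_table):
        fit = incidence.fit_model(district_table, 1)
        bands = incidence.intervals(fit)
        assert np.allclose(bands["pi_halfwidth"], 0.0, atol=1e-6)

    def test_prediction_interval_coverage(self):
        """A fresh draw lands inside the 99% PI about 99% of the time."""
        rng_master = np.random.default_rng(2024)
        inside = total = 0
        for _ in range(500):
            rng = np.random.default_rng(rng_master.integers(2**31))
            n = 40
            S = rng.lognormal(8, 1, n).round()
            F = rng.uniform(0, 0.3, n)
            mu = 10.0 + 1e-3 * F * S
            y = mu + rng.normal(0, 1.0, n)
            table = pd.DataFrame({"district_id": np.arange(n),
                                  "rural_pop": S, "F": F,
                                  "observed_incidence": y})
            fit = incidence.fit_model(table, 1)
            bands = incidence.intervals(fit, level=0.99)
            ynew = mu + rng.normal(0, 1.0, n)
            inside += int(np.sum((ynew >= bands["pi_low"])
                                 & (ynew <= bands["pi_high"])))
            total += n
        cover = inside / total
        assert 0.975 < cover < 0.999

    def test_band_narrowest_at_mean_predictor(self):
        table = make_noisy_table(5, n=80)
        fit = incidence.fit_model(table, 1)
        bands = incidence.intervals(fit)
        assert bands.attrs["ci_halfwidth_at_mean"] <= bands["ci_halfwidth"].min() + 1e-12

    def test_bad_level_rejected(self, district_table):
        fit = incidence.fit_model(district_table, 1)
        with pytest.raises(ValueError):
            incidence.intervals(fit, level=1.5)


class TestResidualDiagnostics:
    @pytest.mark.parametrize("model_id", [1, 3, 4, 5])
    def test_intercept_fits_orthogonal(self, model_id):
        table = make_noisy_table(11, n=100)
        fit = incidence.fit_model(table, model_id)
        r, _ = incidence.residual_fitted_test(fit)
        assert abs(r) < 1e-10

    def test_no_intercept_curvature_detected(self):
        """Model 2 on data needing an intercept leaves structure behind."""
        n = 60
        rng = np.random.default_rng(8)
        S = rng.lognormal(8, 1, n).round()
        F = rng.uniform(0.05, 0.3, n)
        table = pd.DataFrame({"district_id": np.arange(n),
                              "rural_pop": S, "F": F,
                              "observed_incidence": 5.0 + 1e-3 * F * S})
        fit = incidence.fit_model(table, 2)
        r, p = incidence.residual_fitted_test(fit)
        assert abs(r) > 0.1

    def test_degenerate_residuals_flagged(self, district_table):
        fit = incidence.fit_model(district_table, 1)  # perfect fit
        with pytest.warns(UserWarning, match="degenerate"):
            r, p = incidence.residual_fitted_test(fit)
        assert np.isnan(r)


class TestNationalIncidence:
    def test_intercept_total_matches_observed(self):
        table = make_noisy_table(13, n=120)
        for mid in (1, 3, 4, 5):
            fit = incidence.fit_model(table, mid)
            total, _ = incidence.national_incidence(fit)
            assert total == pytest.approx(
                table["observed_incidence"].sum(), abs=1e-8)

    def test_no_intercept_total_differs_on_biased_data(self):
        n = 50
        rng = np.random.default_rng(21)
        S = rng.lognormal(8, 1, n).round()
        F = rng.uniform(0.05, 0.3, n)
        table = pd.DataFrame({"district_id": np.arange(n),
                              "rural_pop": S, "F": F,
                              "observed_incidence": 5.0 + 1e-3 * F * S})
        fit = incidence.fit_model(table, 2)
        total, _ = incidence.national_incidence(fit)
        assert abs(total - table["observed_incidence"].sum()) > 1.0

    def test_noiseless_range_collapses(self, district_table):
        fit = incidence.fit_model(district_table, 1)
        total, (lo, hi) = incidence.national_incidence(fit)
        assert hi - lo < 1e-6


class TestOutliers:
    def test_noiseless_no_flags(self, district_table):
        fit = incidence.fit_model(district_table, 1)
        under, over = incidence.flag_outlier_districts(fit)
        assert under == [] and over == []

    def test_injected_deviation_flagged(self):
        table = make_noisy_table(17, n=100)
        sd = table["observed_incidence"].std()
        table.loc[42, "observed_incidence"] += 10 * sd
        fit = incidence.fit_model(table, 1)
        under, over = incidence.flag_outlier_districts(fit)
        assert 42 in under

    def test_flags_partition(self):
        table = make_noisy_table(19, n=150)
        fit = incidence.fit_model(table, 1)
        under, over = incidence.flag_outlier_districts(fit)
        assert not set(under) & set(over)


class TestCompareModels:
    def test_five_rows_in_order(self):
        comp = incidence.compare_models(make_noisy_table(23, n=80))
        assert list(comp.table["model"]) == [1, 2, 3, 4, 5]

    def test_mass_action_data_prefers_model_1(self):
        """High signal-to-noise mass-action data selects Model 1 by AIC."""
        wins = 0
        for seed in range(100):
            table = make_noisy_table(seed + 1000, n=150, target_r2=0.9)
            comp = incidence.compare_models(table)
            wins += comp.best_model == 1
        assert wins >= 90

    def test_population_only_data_prefers_population_model(self):
        """Data with no F effect: the population-only structure wins, or
        the mass-action fit finds no evidence for theta. (The product
        F*S proxies S, so the two structures compete.)"""
        rng = np.random.default_rng(29)
        n = 150
        S = rng.lognormal(8, 1, n).round()
        F = rng.uniform(0, 0.3, n)
        y = 0.5 + 3e-4 * S + rng.normal(0, 0.3 * np.std(3e-4 * S), n)
        table = pd.DataFrame({"district_id": np.arange(n), "rural_pop": S,
                              "F": F, "observed_incidence": np.maximum(y, 0)})
        comp = incidence.compare_models(table)
        if comp.best_model == 1:
            ci = incidence.confint_params(comp.fits[1], level=0.99)
            assert ci.loc["theta", "low"] <= 0 <= ci.loc["theta", "high"]
        else:
            assert comp.best_model in (3, 5)


class TestMultiSpecies:
    def test_single_species_reduces_to_model_1(self, district_table):
        F1 = district_table[["F"]].rename(columns={"F": "asper"})
        multi = incidence.fit_multi_species(F1, district_table)
        base = incidence.fit_model(district_table, 1)
        assert multi.params["alpha"] == pytest.approx(base.params["alpha"],
                                                      abs=1e-10)
        assert multi.params["theta_asper"] == pytest.approx(
            base.params["theta"], abs=1e-10)

    def test_two_species_theta_ratio_recovered(self):
        """theta_1 = 2*theta_2 truth: ratio CI spans 2 at a fixed seed."""
        rng = np.random.default_rng(31)
        n = 150
        S = rng.lognormal(8, 1, n).round()
        F = pd.DataFrame({"sp1": rng.uniform(0, 0.3, n),
                          "sp2": rng.uniform(0, 0.3, n)})
        th1, th2 = 2e-3, 1e-3
        mu = 5.0 + th1 * F["sp1"] * S + th2 * F["sp2"] * S
        y = np.maximum(mu + rng.normal(0, 0.2 * mu.std(), n), 0.0)
        table = pd.DataFrame({"district_id": np.arange(n), "rural_pop": S,
                              "F": F["sp1"], "observed_incidence": y})
        fit = incidence.fit_multi_species(F, table)
        t1, t2 = fit.params["theta_sp1"], fit.params["theta_sp2"]
        # Delta-method 99% CI for the ratio.
        cov = fit.cov_params
        var_ratio = (cov.loc["theta_sp1", "theta_sp1"] / t2**2
                     + t1**2 * cov.loc["theta_sp2", "theta_sp2"] / t2**4
                     - 2 * t1 * cov.loc["theta_sp1", "theta_sp2"] / t2**3)
        z = stats.norm.ppf(0.995)
        half = z * np.sqrt(var_ratio)
        assert t1 / t2 - half <= 2.0 <= t1 / t2 + half

    def test_column_permutation_permutes_coefficients(self):
        rng = np.random.default_rng(33)
        n = 60
        S = rng.lognormal(8, 1, n).round()
        F = pd.DataFrame({"a": rng.uniform(0, 0.3, n),
                          "b": rng.uniform(0, 0.3, n)})
        y = 1 + 1e-3 * F["a"] * S + 2e-3 * F["b"] * S + rng.normal(0, 0.5, n)
        table = pd.DataFrame({"district_id": np.arange(n), "rural_pop": S,
                              "F": F["a"], "observed_incidence": y})
        f1 = incidence.fit_multi_species(F, table)
        f2 = incidence.fit_multi_species(F[["b", "a"]], table)
        assert f1.params["theta_a"] == pytest.approx(f2.params["theta_a"])
        assert f1.params["theta_b"] == pytest.approx(f2.params["theta_b"])

    def test_collinear_species_named(self):
        rng = np.random.default_rng(35)
        n = 40
        S = rng.lognormal(8, 1, n).round()
        fa = rng.uniform(0, 0.3, n)
        F = pd.DataFrame({"a": fa, "b": 2 * fa})
        table = pd.DataFrame({"district_id": np.arange(n), "rural_pop": S,
                              "F": fa,
                              "observed_incidence": rng.uniform(0, 5, n)})
        with pytest.raises(ValueError, match="'a', 'b'"):
            incidence.fit_multi_species(F, table)
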