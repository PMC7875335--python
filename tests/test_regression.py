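import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snakerisk import regression as reg
from snakerisk.synthetic import SyntheticConfig, generate_country, records_to_frames


@pytest.fixture(scope="module")
def recovery_data(recovery_config):
    cfg = SyntheticConfig(**recovery_config, seed=3)
    records, _, truth = generate_country(cfg)
    surv, drv = records_to_frames(records)
    std, _ = reg.standardize(drv[["temperature", "urban_pct"]])
    return surv["cases"].to_numpy(float), std, truth


class TestStandardize:
    def test_zero_mean_unit_sd(self, small_frames):
        _, drv = small_frames
        std, _ = reg.standardize(drv[["temperature", "elevation", "gdp_per_capita"]])
        assert np.allclose(std.mean(), 0, atol=1e-12)
        assert np.allclose(std.std(ddof=0), 1, atol=1e-12)

    def test_dichotomous_passes_through(self, small_frames):
        _, drv = small_frames
        std, params = reg.standardize(drv[["temperature", "habitat_tropical"]])
        assert np.array_equal(std["habitat_tropical"], drv["habitat_tropical"])
        assert tuple(params["habitat_tropical"]) == (0.0, 1.0)

    def test_round_trip_inverse(self, small_frames):
        _, drv = small_frames
        cols = ["temperature", "precipitation", "elevation"]
        std, params = reg.standardize(drv[cols])
        back = reg.inverse_standardize(std, params)
        assert np.allclose(back, drv[cols].astype(float))

    def test_zero_variance_column_excluded_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            std, _ = reg.standardize(df)
        assert list(std.columns) == ["a"]


class TestUnivariateScreen:
    def test_planted_effect_recovered_and_retained(self):
        cfg = SyntheticConfig(n_states=2, grid_rows=40, grid_cols=50,
                              beta={"temperature": 0.5}, beta0=math.log(10),
                              theta=2.0, seed=21)
        records, _, _ = generate_country(cfg)
        surv, drv = records_to_frames(records)
        std, _ = reg.standardize(drv[["temperature"]])
        res = reg.univariate_screen(surv["cases"], std["temperature"], "temperature")
        assert res.retained
        assert res.ci_low <= math.exp(0.5) <= res.ci_high

    def test_null_driver_rarely_retained(self):
        # independent covariate: retention is the 5% type-I error
        rng = np.random.default_rng(0)
        retained = 0
        n_reps = 40
        for rep in range(n_reps):
            y = rng.negative_binomial(n=2.0, p=2.0 / (2.0 + 10.0), size=800)
            x = rng.standard_normal(800)
            res = reg.univariate_screen(y, x, "noise")
            retained += res.retained
        assert retained <= 6  # Binomial(40, 0.05) upper tail, P < 1e-4

    def test_negated_driver_gives_reciprocal_rr(self, small_frames):
        surv, drv = small_frames
        std, _ = reg.standardize(drv[["temperature"]])
        a = reg.univariate_screen(surv["cases"], std["temperature"], "t")
        b = reg.univariate_screen(surv["cases"], -std["temperature"], "t")
        assert a.rr == pytest.approx(1 / b.rr, rel=1e-6)


class TestVif:
    def test_orthogonal_columns_give_unit_vif(self):
        n = 64
        X = pd.DataFrame(
            {f"c{i}": np.cos(2 * np.pi * (i + 1) * np.arange(n) / n) for i in range(3)}
        )
        assert np.allclose(reg.vif(X), 1.0, atol=1e-8)

    def test_near_duplicate_columns_flagged(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=200)
        X = pd.DataFrame({"x1": x1, "x2": x1 + rng.normal(0, 1e-4, 200),
                          "x3": rng.normal(size=200)})
        v = reg.vif(X)
        assert v["x1"] > 5 and v["x2"] > 5 and v["x3"] < 5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(120, 6)), columns=list("abcdef"))
        X["b"] = X["a"] * 0.7 + X["b"] * 0.3  # induce some collinearity
        got = reg.vif(X)
        # oracle: R^2 via numpy lstsq with explicit intercept
        for col in X.columns:
            others = X.drop(columns=col).to_numpy()
            A = np.column_stack([np.ones(len(X)), others])
            y = X[col].to_numpy()
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
            assert got[col] == pytest.approx(1 / (1 - r2), rel=1e-8)

    def test_input_shape_validation(self):
        with pytest.raises(ValueError):
            reg.vif(pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(ValueError):
            reg.vif(pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4))))


class TestPearsonFilter:
    def test_identical_columns_one_excluded(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": x, "c": np.cos(x)})
        retained, excluded, _ = reg.pearson_filter(X)
        assert retained == ["a", "c"]
        assert excluded[0][0] == "b"

    def test_strength_decides_which_member_drops(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": x})
        retained, _, _ = reg.pearson_filter(X, strength={"a": 0.1, "b": 0.9})
        assert retained == ["b"]

    def test_independent_columns_not_excluded(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(1000, 5)), columns=list("abcde"))
        retained, excluded, _ = reg.pearson_filter(X, threshold=0.8)
        assert retained == list("abcde") and not excluded

    def test_constant_column_excluded_with_reason(self):
        X = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
        _, excluded, _ = reg.pearson_filter(X)
        assert excluded == [("b", "constant column: correlation undefined")]

    def test_correlation_matches_hand_computation(self):
        a = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        b = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        _, _, corr = reg.pearson_filter(pd.DataFrame({"a": a, "b": b}), threshold=0.99)
        za, zb = a - a.mean(), b - b.mean()
        expected = (za @ zb) / math.sqrt((za @ za) * (zb @ zb))
        assert corr.loc["a", "b"] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)


class TestFitCountModel:
    def test_intercept_only_poisson_closed_form(self):
        y = np.array([0, 1, 2, 3, 10, 4])
        fit = reg.fit_count_model(y, pd.DataFrame(index=range(6)), family="poisson")
        assert fit.params["const"] == pytest.approx(math.log(y.mean()), abs=1e-8)

    def test_nb_on_poisson_data_approaches_poisson_coefficients(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(3000)
        y = rng.poisson(np.exp(1.0 + 0.4 * x))
        X = pd.DataFrame({"x": x})
        po = reg.fit_count_model(y, X, family="poisson")
        nb = reg.fit_count_model(y, X, family="nb")
        assert nb.theta > 50  # dispersion pushed toward the Poisson limit
        assert np.allclose(nb.params, po.params, atol=1e-3)

    def test_rr_equals_exp_beta_with_wald_interval(self, recovery_data):
        y, std, _ = recovery_data
        fit = reg.fit_count_model(y, std, family="nb")
        for d in ("temperature", "urban_pct"):
            assert fit.rr.loc[d, "RR"] == pytest.approx(math.exp(fit.params[d]))
            assert fit.rr.loc[d, "ci_low"] == pytest.approx(
                math.exp(fit.params[d] - reg.Z95 * fit.se[d])
            )
            assert fit.rr.loc[d, "ci_low"] <= fit.rr.loc[d, "RR"] <= fit.rr.loc[d, "ci_high"]

    def test_rr_invariant_to_covariate_units(self, small_frames):
        surv, drv = small_frames
        y = surv["cases"].to_numpy(float)
        std1, _ = reg.standardize(drv[["temperature"]])
        rescaled = drv[["temperature"]] * 1000.0 + 42.0
        std2, _ = reg.standardize(rescaled)
        f1 = reg.fit_count_model(y, std1, family="poisson")
        f2 = reg.fit_count_model(y, std2, family="poisson")
        assert f1.rr.loc["temperature", "RR"] == pytest.approx(
            f2.rr.loc["temperature", "RR"], rel=1e-8
        )

    def test_nb_loglik_dominates_poisson_solution(self, recovery_data):
        # at the NB ML solution the NB likelihood is at least that of the
        # Poisson coefficient vector under any finite dispersion
        y, std, _ = recovery_data
        nb = reg.fit_count_model(y, std, family="nb")
        po = reg.fit_count_model(y, std, family="poisson")
        X = np.column_stack([np.ones(len(y)), std.to_numpy()])
        mu_po = np.exp(X @ po.params.to_numpy())
        for theta in (0.5, 1.2, 5.0, 50.0):
            assert nb.llf >= reg.nb_loglike(y, mu_po, theta) - 1e-6

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="rank"):
            reg.fit_count_model(np.array([1, 2, 3, 4]), X)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            reg.fit_count_model(np.array([1, -2]), pd.DataFrame({"x": [0.0, 1.0]}))

    def test_population_offset_changes_intercept_not_slopes_much(self, recovery_data):
        y, std, _ = recovery_data
        offset = np.log(np.full(len(y), 2.0))
        base = reg.fit_count_model(y, std, family="poisson")
        off = reg.fit_count_model(y, std, family="poisson", offset=offset)
        assert off.params["const"] == pytest.approx(base.params["const"] - math.log(2.0), abs=1e-6)
        assert np.allclose(off.params[["temperature", "urban_pct"]],
                           base.params[["temperature", "urban_pct"]], atol=1e-8)


class TestCompareModels:
    def test_nb_beats_poisson_on_overdispersed_data(self, recovery_data):
        y, std, _ = recovery_data
        nb = reg.fit_count_model(y, std, family="nb")
        po = reg.fit_count_model(y, std, family="poisson")
        rep = reg.compare_models([po, nb], seed=0)
        assert rep["criterion"] == "DIC"
        assert rep["best"] == "nb"
        assert rep["aic_ranking"][0] == "nb"

    def test_identical_fits_tie(self, recovery_data):
        y, std, _ = recovery_data
        po = reg.fit_count_model(y, std, family="poisson")
        rep = reg.compare_models([po, po], seed=0)
        assert rep["tie"] and rep["best"] is None

    def test_equidispersed_data_favors_poisson_or_near_tie(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(4000)
        y = rng.poisson(np.exp(1.5 + 0.3 * x))
        X = pd.DataFrame({"x": x})
        po = reg.fit_count_model(y, X, family="poisson")
        nb = reg.fit_count_model(y, X, family="nb")
        rep = reg.compare_models([po, nb], seed=1)
        dics = rep["models"]
        assert rep["best"] == "poisson" or abs(dics["poisson"]["dic"] - dics["nb"]["dic"]) < 2

    def test_differing_data_rejected(self, recovery_data):
        y, std, _ = recovery_data
        a = reg.fit_count_model(y, std, family="poisson")
        b = reg.fit_count_model(y[:-1], std.iloc[:-1], family="poisson")
        with pytest.raises(ValueError, match="identical data"):
            reg.compare_models([a, b])


class TestIncidenceGroupContrast:
    def test_planted_shift_detected(self):
        rng = np.random.default_rng(6)
        n = 400
        inc = pd.Series(rng.uniform(0, 100, n))
        shifted = rng.standard_normal(n) + 2.0 * (inc > inc.median())
        flat = rng.standard_normal(n)
        out = reg.incidence_group_contrast(inc, pd.DataFrame({"s": shifted, "f": flat}))
        assert out.loc["s", "p"] < 1e-3
        assert out.loc["f", "p"] > 1e-3

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            inc = pd.Series(rng.uniform(0, 10, 60))
            drv = pd.DataFrame({"x": rng.standard_normal(60)})
            pvals.append(reg.incidence_group_contrast(inc, drv).loc["x", "p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_identical_groups_give_zero_t(self):
        inc = pd.Series([1.0, 1.0, 5.0, 5.0])
        drv = pd.DataFrame({"x": [3.0, 3.0, 3.0, 3.0]})
        out = reg.incidence_group_contrast(inc, drv)
        assert out.loc["x", "t"] == 0.0 and out.loc["x", "p"] == 1.0

    def test_degenerate_group_skipped_with_reason(self):
        inc = pd.Series([1.0, 2.0, 3.0])  # high group has a single member
        drv = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        out = reg.incidence_group_contrast(inc, drv)
        assert "degenerate" in out.loc["x", "note"]


class TestDriverPipeline:
    def test_all_nine_drivers_survive_without_planted_collinearity(self, medium_country):
        # mirrors the real analysis: nine screened drivers, none collinear,
        # all retained into the multivariate model
        _, records, _, _ = medium_country
        surv, drv = records_to_frames(records)
        from snakerisk.synthetic import DRIVER_NAMES

        result = reg.driver_pipeline(
            surv["cases"].to_numpy(float), drv[list(DRIVER_NAMES)], dic_draws=200, seed=0
        )
        assert len(result["retained"]) == 9
        assert (result["collinearity"].vif <= 5).all()
        assert result["selection"]["best"] == "nb"
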