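import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lepmon import (TrimModel, annualize, classify_trend, fit_trim,
                    overall_multiplicative_slope, select_model)
from lepmon.trend import NonConvergenceError


def _random_matrix(shape=(5, 6), seed=0, lam=8.0):
    rng = np.random.default_rng(seed)
    return rng.poisson(lam, size=shape).astype(float) + 1.0


class TestFitting:
    def test_homogeneous_data_flat(self):
        res = fit_trim(np.full((4, 6), 9.0), model=2)
        assert res.slope_param == pytest.approx(0.0, abs=1e-10)
        m, se = res.overall_slope()
        assert m == pytest.approx(1.0, abs=1e-10)
        assert res.deviance == pytest.approx(0.0, abs=1e-10)

    def test_exact_geometric_series(self):
        res = fit_trim(np.array([[10., 20., 40., 80.]]), model=2)
        m, _ = res.overall_slope()
        assert m == pytest.approx(2.0, abs=1e-9)
        assert res.deviance == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("model", [1, 2, 3])
    def test_matches_statsmodels_glm(self, model):
        mat = _random_matrix(seed=model)
        trim = TrimModel(mat, model=model)
        res = trim.fit()
        X, y = trim._design()
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(res.params, glm.params, atol=1e-8)
        np.testing.assert_allclose(res.cov_params / res.sigma2,
                                   glm.cov_params(), atol=1e-8)
        assert res.deviance == pytest.approx(glm.deviance, abs=1e-8)

    def test_deviance_nesting(self):
        for seed in range(10):
            mat = _random_matrix(seed=seed)
            g = [fit_trim(mat, model=k).deviance for k in (1, 2, 3)]
            assert g[0] >= g[1] - 1e-9
            assert g[1] >= g[2] - 1e-9

    def test_fitted_totals_conserved_per_site(self):
        mat = _random_matrix(seed=42)
        for model in (1, 2, 3):
            res = fit_trim(mat, model=model)
            np.testing.assert_allclose(res.fitted.sum(axis=1),
                                       mat.sum(axis=1), rtol=1e-8)

    def test_j2_models_agree(self):
        for seed in range(10):
            mat = _random_matrix(shape=(4, 2), seed=seed)
            m2 = fit_trim(mat, model=2).overall_slope()[0]
            m3 = fit_trim(mat, model=3).overall_slope()[0]
            assert m2 == pytest.approx(m3, abs=1e-8)

    def test_missing_cells_restrict_likelihood(self):
        mat = _random_matrix(seed=1).astype(float)
        mat[0, 0] = np.nan
        res = fit_trim(mat, model=3)
        # fitted value for the hole is model-based and positive
        assert res.fitted.iloc[0, 0] > 0
        assert res.df_resid == mat.size - 1 - (5 + 6 - 1)

    def test_all_zero_site_dropped_with_warning(self):
        mat = _random_matrix(seed=2)
        mat[2, :] = 0.0
        with pytest.warns(UserWarning, match="dropping site"):
            res = fit_trim(mat, model=2)
        assert res.model.n_sites == 4

    def test_doubling_yearly_totals_model3(self):
        base = np.array([[5., 10., 20., 40.], [3., 6., 12., 24.]])
        res = fit_trim(base, model=3)
        m, _ = res.overall_slope()
        assert m == pytest.approx(2.0, abs=1e-8)

    def test_model1_has_no_slope(self):
        res = fit_trim(_random_matrix(), model=1)
        with pytest.raises(ValueError):
            res.overall_slope()

    def test_annual_site_matrix_input(self, records):
        species = records["species_id"].iloc[0]
        mat = annualize(records, species)
        res = fit_trim(mat, model=2)
        assert res.model.species_id == species
        assert res.fitted.shape == mat.counts.shape

    def test_overdispersion_floor(self):
        res = fit_trim(np.full((4, 6), 9.0), model=2)
        assert res.sigma2 == 1.0  # underdispersion floored at 1

    def test_delta_method_at_null(self):
        # beta ~ 0: SE(m) equals SE(beta) to first order
        mat = np.full((3, 5), 20.0)
        res = fit_trim(mat, model=2)
        I = res.model.n_sites
        se_beta = np.sqrt(res.cov_params[I, I])
        _, se_m = res.overall_slope()
        assert se_m == pytest.approx(se_beta, rel=1e-9)


class TestClassifyTrend:
    @pytest.mark.parametrize("m,se,expected", [
        (1.159, 0.059, "moderate increase"),
        (1.189, 0.066, "strong increase"),
        (0.896, 0.127, "uncertain"),
        (1.0, 0.01, "stable"),
        (0.80, 0.02, "steep decline"),
        (0.97, 0.005, "moderate decline"),
    ])
    def test_categories(self, m, se, expected):
        assert classify_trend(m, se) == expected

    def test_covers_plane(self):
        cats = {"strong increase", "moderate increase", "stable", "uncertain",
                "moderate decline", "steep decline"}
        seen = set()
        for m in np.linspace(0.5, 1.6, 45):
            for se in np.linspace(0.0, 0.3, 40):
                c = classify_trend(m, se)
                assert c in cats
                seen.add(c)
        assert seen == cats

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_trend(-1.0, 0.1)
        with pytest.raises(ValueError):
            classify_trend(1.0, -0.1)


class TestModelSelection:
    def test_single_candidate_returned(self):
        res = fit_trim(_random_matrix(), model=2)
        best, flag = select_model([res])
        assert best is res and flag is False

    def test_linear_data_prefers_model2(self):
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(30):
            mu = 20 * 1.15 ** np.arange(6)[None, :] * np.ones((5, 1))
            mat = rng.poisson(mu).astype(float)
            fits = [fit_trim(mat, model=k) for k in (2, 3)]
            best, _ = select_model(fits)
            wins += best.model.model == 2
        assert wins >= 27

    def test_site_only_data_prefers_model1(self):
        rng = np.random.default_rng(1)
        wins = 0
        for _ in range(30):
            mu = np.array([5., 10., 20., 40., 15.])[:, None] * np.ones((1, 6))
            mat = rng.poisson(mu).astype(float)
            fits = [fit_trim(mat, model=k) for k in (1, 2, 3)]
            best, _ = select_model(fits)
            wins += best.model.model == 1
        # with AIC = G2 - 2 df, spurious time effects enter when the
        # deviance drop beats twice the extra df (~20% of null draws)
        assert wins >= 21

    def test_slope_wrapper(self):
        res = fit_trim(_random_matrix(), model=2)
        assert overall_multiplicative_slope(res) == res.overall_slope()


class TestRecovery:
    def test_parameter_recovery_short(self):
        # 40-rep version; the 200-rep study-scale run is in acceptance
        rng = np.random.default_rng(7)
        m_hats, covered = [], 0
        for _ in range(40):
            mu = 10 * 1.10 ** np.arange(8)[None, :] * np.ones((10, 1))
            mat = rng.poisson(mu).astype(float)
            res = fit_trim(mat, model=2)
            m, se = res.overall_slope()
            m_hats.append(m)
            covered += abs(m - 1.10) <= 1.96 * se
        assert np.mean(m_hats) == pytest.approx(1.10, abs=0.01)
        assert covered / 40 >= 0.85

    def test_summary_mentions_category(self):
        res = fit_trim(np.array([[10., 20., 40., 80.]]), model=2)
        text = res.summary()
        assert "multiplicative slope" in text
        assert "TRIM model 2" in text


def test_plot_returns_axes():
    import matplotlib
    matplotlib.use("Agg")
    res = fit_trim(_random_matrix(), model=3)
    ax = res.plot()
    assert ax.get_ylabel() == "summed count"
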