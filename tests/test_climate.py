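import numpy as np
import pandas as pd
import pytest

from lepmon import build_covariates, degree_days, simulate_climate, stepwise_regress
from lepmon.climate import regression_stats


def _flat_climate(days=120, tmax=30.0, tmin=20.0, start="2020-01-01"):
    dates = pd.date_range(start, periods=days, freq="D")
    return pd.DataFrame({"date": dates, "tmax": tmax, "tmin": tmin,
                         "rainfall": 1.0, "solar_rad": 15.0,
                         "soil_humidity": 0.4})


class TestDegreeDays:
    def test_constant_temperature(self):
        clim = _flat_climate()
        # mean (30+20)/2 = 25; 15 deg above base over 30 days
        assert degree_days(clim, "2020-03-01", 30, 10.0) == pytest.approx(450.0)

    def test_all_below_base_floors_at_zero(self):
        clim = _flat_climate(tmax=8.0, tmin=2.0)
        assert degree_days(clim, "2020-03-01", 30, 10.0) == 0.0

    def test_matches_day_by_day_enumeration(self):
        daily, _ = simulate_climate(1, seed=3)
        end = pd.Timestamp("2009-07-15")
        window = daily[(daily["date"] >= end - pd.Timedelta(days=30))
                       & (daily["date"] < end)]
        brute = sum(max(0.0, (r.tmax + r.tmin) / 2 - 10.0)
                    for r in window.itertuples())
        assert degree_days(daily, end, 30, 10.0) == pytest.approx(brute)

    def test_monotone_in_temperature_and_window(self):
        clim = _flat_climate()
        base = degree_days(clim, "2020-03-01", 15, 10.0)
        warmer = _flat_climate(tmax=32.0)
        assert degree_days(warmer, "2020-03-01", 15, 10.0) > base
        assert degree_days(clim, "2020-03-01", 30, 10.0) > base

    def test_missing_days_reported(self):
        clim = _flat_climate().drop(index=[40, 41])
        with pytest.raises(ValueError, match="missing"):
            degree_days(clim, "2020-03-01", 30, 10.0)


class TestBuildCovariates:
    @pytest.fixture()
    def survey_frame(self):
        rows = []
        for year in range(2009, 2017):
            for t, month in enumerate((3, 5, 9, 11), start=1):
                rows.append({"date": pd.Timestamp(year, month, 15),
                             "year": year, "survey_index": t})
        return pd.DataFrame(rows)

    def test_one_row_per_survey(self, survey_frame):
        daily, enso = simulate_climate(8, seed=0)
        cov = build_covariates(daily, enso, survey_frame)
        assert len(cov) == 32
        for col in ("dd15", "dd30", "tmin15", "tmin30", "enso",
                    "rain_month_sum"):
            assert col in cov.columns
        assert (cov["dd15"] >= 0).all() and (cov["dd30"] >= 0).all()

    def test_constant_climate_flagged(self, survey_frame):
        daily = _flat_climate(days=8 * 366, start="2009-01-01")
        enso = pd.DataFrame({"year": np.repeat(range(2009, 2017), 12),
                             "month": list(range(1, 13)) * 8, "enso": 0.0})
        with pytest.warns(UserWarning, match="zero-variance"):
            cov = build_covariates(daily, enso, survey_frame)
        assert "tmax_day" in cov.attrs["constant_columns"]

    def test_lag_window_excludes_survey_day(self, survey_frame):
        # a temperature spike on the survey day must not leak into dd15/dd30
        daily = _flat_climate(days=8 * 366, start="2009-01-01",
                              tmax=9.0, tmin=9.0)
        spike_day = pd.Timestamp(2009, 3, 15)
        daily.loc[daily["date"] == spike_day, ["tmax", "tmin"]] = 40.0
        enso = pd.DataFrame({"year": np.repeat(range(2009, 2017), 12),
                             "month": list(range(1, 13)) * 8, "enso": 0.0})
        with pytest.warns(UserWarning):
            cov = build_covariates(daily, enso, survey_frame)
        first = cov[(cov.year == 2009) & (cov.survey_index == 1)].iloc[0]
        assert first["dd15"] == 0.0 and first["dd30"] == 0.0
        # but the spike does enter the *next* survey's 30-day window? no —
        # May window starts Apr 15; it must stay clear of the March spike
        may = cov[(cov.year == 2009) & (cov.survey_index == 2)].iloc[0]
        assert may["dd30"] == 0.0


class TestStepwise:
    def _design(self, n=32, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"x{j}" for j in range(10)])
        return rng, X

    def test_true_predictors_found(self):
        rng, X = self._design(seed=1)
        y = X["x0"] + X["x1"] - X["x2"] + rng.normal(0, 1, len(X))
        res = stepwise_regress(y, X)
        assert {"x0", "x1", "x2"} <= set(res.selected)

    def test_pure_noise_mostly_empty(self):
        # few candidates: best-of-k AIC entry makes spurious inclusion rarer
        empties = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(32, 3)),
                             columns=["x0", "x1", "x2"])
            y = rng.normal(size=32)
            res = stepwise_regress(y, X)
            empties += len(res.selected) == 0
        assert empties >= 16  # majority of replicates

    def test_duplicate_predictor_screened(self):
        rng, X = self._design(seed=2)
        X["dup"] = X["x0"]
        y = X["x0"] + rng.normal(0, 0.5, len(X))
        res = stepwise_regress(y, X)
        assert len(res.dropped_collinear) >= 1
        assert not {"x0", "dup"} <= set(res.selected)

    def test_statistics_identities(self):
        rng, X = self._design(seed=3)
        y = 2 * X["x0"] + rng.normal(0, 1, len(X))
        res = stepwise_regress(y, X)
        k = len(res.selected)
        n = res.n_obs
        adj = 1 - (1 - res.r_squared) * (n - 1) / (n - k - 1)
        f = (res.r_squared / k) / ((1 - res.r_squared) / (n - k - 1))
        assert res.adj_r_squared == pytest.approx(adj, abs=1e-12)
        assert res.f_statistic == pytest.approx(f, abs=1e-9)
        assert res.f_df == (k, n - k - 1)

    def test_zero_variance_response(self):
        _, X = self._design()
        with pytest.raises(ValueError):
            stepwise_regress(np.ones(len(X)), X)

    def test_standardized_coefficients_scale_free(self):
        rng, X = self._design(seed=4)
        y = 3 * X["x0"] + rng.normal(0, 0.5, len(X))
        res1 = stepwise_regress(y, X)
        X2 = X.copy()
        X2["x0"] = X2["x0"] * 100
        res2 = stepwise_regress(y, X2)
        assert res1.std_coefficients["x0"] == pytest.approx(
            res2.std_coefficients["x0"], abs=1e-9)


def test_regression_stats_identity_values():
    adj, f, p = regression_stats(0.538, n=11, k=2)
    assert adj == pytest.approx(1 - (1 - 0.538) * 10 / 8, abs=1e-12)
    assert f == pytest.approx((0.538 / 2) / ((1 - 0.538) / 8), abs=1e-12)
    assert 0 < p < 1
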