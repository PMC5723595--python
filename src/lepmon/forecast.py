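"""Seasonal time-series diagnostics and short-horizon survey forecasts.

Survey-level abundance series (four surveys a year) are screened with
ACF/PACF plots and forecast two years ahead (eight surveys) with a seasonal
ARIMA of period 4.  An optional harmonic pre-step removes a single
sine/cosine pair at the seasonal period before fitting and adds it back to
the forecasts, for series dominated by a fixed annual cycle.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as sm_acf, pacf as sm_pacf
from statsmodels.tsa.statespace.sarimax import SARIMAX

__all__ = ["acf_pacf", "SeasonalForecaster", "ForecastResults",
           "forecast_seasonal"]

SEASON = 4


def acf_pacf(series, max_lag: int = 12) -> pd.DataFrame:
    """Sample ACF and PACF with the +/-1.96/sqrt(n) white-noise band.

    Returns a frame indexed by lag 0..max_lag with columns acf, pacf and
    band.  A constant series has no defined correlation beyond lag 0; those
    entries are NaN and the frame carries ``attrs['degenerate'] = True``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n <= max_lag:
        raise ValueError("series must be longer than max_lag")
    band = 1.96 / np.sqrt(n)
    lags = np.arange(max_lag + 1)
    if np.ptp(x) == 0:
        out = pd.DataFrame({"acf": np.nan, "pacf": np.nan, "band": band},
                           index=lags)
        out.loc[0, ["acf", "pacf"]] = 1.0
        out.attrs["degenerate"] = True
        return out
    a = sm_acf(x, nlags=max_lag, fft=True)
    p = sm_pacf(x, nlags=min(max_lag, n // 2 - 1), method="ywm")
    p = np.concatenate([p, np.full(max_lag + 1 - p.size, np.nan)])
    out = pd.DataFrame({"acf": a, "pacf": p, "band": band}, index=lags)
    out.attrs["degenerate"] = False
    return out


def _harmonics(n: int) -> np.ndarray:
    t = np.arange(n)
    return np.column_stack([np.sin(2 * np.pi * t / SEASON),
                            np.cos(2 * np.pi * t / SEASON)])


@dataclasses.dataclass
class ForecastResults:
    """Point forecasts with 95% bounds plus the fitted model's metadata."""

    history: np.ndarray
    forecast: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    order: tuple
    seasonal_order: tuple
    aic: float
    harmonic_detrended: bool

    @property
    def horizon(self) -> int:
        return self.forecast.size

    def summary(self) -> str:
        head = (f"Seasonal ARIMA {self.order}x{self.seasonal_order} "
                f"(AIC {self.aic:.2f}"
                + (", harmonic pre-step)" if self.harmonic_detrended else ")"))
        rows = [f"  t+{k + 1}: {f:.3f}  [{lo:.3f}, {hi:.3f}]"
                for k, (f, lo, hi) in
                enumerate(zip(self.forecast, self.lower, self.upper))]
        return "\n".join([head] + rows)

    def plot(self, ax=None):
        """History, point forecasts and the 95% band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        n = self.history.size
        t_fut = np.arange(n, n + self.horizon)
        ax.plot(np.arange(n), self.history, color="0.4", label="history")
        ax.plot(t_fut, self.forecast, "r--", label="forecast")
        ax.fill_between(t_fut, self.lower, self.upper, color="r", alpha=0.15,
                        label="95% interval")
        ax.set_xlabel("survey")
        ax.set_ylabel("index")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "forecast": self.forecast.tolist(),
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "order": list(self.order),
            "seasonal_order": list(self.seasonal_order),
            "aic": float(self.aic),
        }


class SeasonalForecaster:
    """Seasonal ARIMA (period 4) forecaster for survey index series.

    Parameters mirror SARIMAX; ``auto=True`` searches a small order grid by
    AIC.  ``harmonic_detrend=True`` regresses out one sine/cosine pair at
    the seasonal period first and forecasts the residual process.
    """

    def __init__(self, series, order=(1, 0, 0), seasonal_order=(1, 0, 0, SEASON),
                 harmonic_detrend: bool = False, auto: bool = False):
        x = np.asarray(series, dtype=float)
        if not np.isfinite(x).all():
            raise ValueError("series contains non-finite values")
        if x.size < 3 * SEASON:
            raise ValueError("need at least 3 complete seasonal cycles")
        self.series = x
        self.order = tuple(order)
        self.seasonal_order = tuple(seasonal_order)
        self.harmonic_detrend = harmonic_detrend
        self.auto = auto

    def _candidate_orders(self):
        if not self.auto:
            yield self.order, self.seasonal_order
            return
        for p in (0, 1):
            for q in (0, 1):
                for P in (0, 1):
                    for D in (0, 1):
                        if p + q + P == 0 and D == 0:
                            continue
                        yield (p, 0, q), (P, D, 0, SEASON)

    def fit(self, horizon: int = 8) -> ForecastResults:
        y = self.series.copy()
        trend_part = np.zeros(horizon)
        if self.harmonic_detrend:
            H = _harmonics(y.size)
            X = np.column_stack([np.ones(y.size), H])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            y = y - X @ coef
            t_fut = np.arange(y.size, y.size + horizon)
            Hf = np.column_stack([np.sin(2 * np.pi * t_fut / SEASON),
                                  np.cos(2 * np.pi * t_fut / SEASON)])
            trend_part = coef[0] + Hf @ coef[1:]

        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for order, sorder in self._candidate_orders():
                try:
                    trend = "c" if (order[1] == 0 and sorder[1] == 0
                                    and not self.harmonic_detrend) else None
                    res = SARIMAX(y, order=order, seasonal_order=sorder,
                                  trend=trend).fit(disp=0)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if best is None or res.aic < best[0]:
                    best = (res.aic, order, sorder, res)
        if best is None:
            raise RuntimeError("no seasonal ARIMA candidate could be fitted")
        aic, order, sorder, res = best
        fc = res.get_forecast(horizon)
        point = np.asarray(fc.predicted_mean) + trend_part
        ci = np.asarray(fc.conf_int(alpha=0.05))
        lower = ci[:, 0] + trend_part
        upper = ci[:, 1] + trend_part
        return ForecastResults(history=self.series, forecast=point,
                               lower=lower, upper=upper, order=order,
                               seasonal_order=sorder, aic=float(aic),
                               harmonic_detrended=self.harmonic_detrend)


def forecast_seasonal(series, horizon: int = 8, **kwargs) -> ForecastResults:
    """Fit the default seasonal model and forecast *horizon* surveys ahead."""
    return SeasonalForecaster(series, **kwargs).fit(horizon=horizon)
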