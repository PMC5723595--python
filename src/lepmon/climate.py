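"""Survey-level climate covariates and stepwise abundance regressions.

Covariates fall in three bands: conditions on the day of the survey,
aggregates over the month of the survey, and lagged summaries over the 15
or 30 days preceding the survey — most importantly accumulated degree-days,
the thermal time available for larval development before the trap night.
Abundance responses are log(x+1) counts per survey; predictor selection is
a collinearity screen followed by bidirectional stepwise AIC.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["degree_days", "build_covariates", "stepwise_regress",
           "RegressionResult", "DEFAULT_BASE_TEMP"]

#: default developmental threshold for degree-day accumulation (deg C)
DEFAULT_BASE_TEMP = 10.0


def _window(climate: pd.DataFrame, end_date, window_days: int) -> pd.DataFrame:
    """The *window_days* days strictly before *end_date* (survey day excluded)."""
    end = pd.Timestamp(end_date)
    start = end - pd.Timedelta(days=window_days)
    idx = climate.set_index("date")
    sel = idx.loc[(idx.index >= start) & (idx.index < end)]
    expected = pd.date_range(start, end - pd.Timedelta(days=1), freq="D")
    missing = expected.difference(sel.index)
    if len(missing):
        gaps = [d.date().isoformat() for d in missing[:5]]
        raise ValueError(f"climate series missing {len(missing)} day(s) in "
                         f"window before {end.date()}: {gaps}...")
    return sel.loc[expected]


def degree_days(climate: pd.DataFrame, end_date, window_days: int = 30,
                base_temp: float = DEFAULT_BASE_TEMP) -> float:
    """Accumulated degree-days over the window preceding *end_date*.

    Daily contribution is max(0, (Tmax+Tmin)/2 - base_temp); the survey day
    itself is excluded (development happened before the trap night).
    """
    win = _window(climate, end_date, window_days)
    daily_mean = (win["tmax"] + win["tmin"]) / 2.0
    return float(np.maximum(0.0, daily_mean - base_temp).sum())


def build_covariates(climate: pd.DataFrame, enso: pd.DataFrame,
                     surveys: pd.DataFrame, lags=(15, 30),
                     base_temp: float = DEFAULT_BASE_TEMP) -> pd.DataFrame:
    """One covariate row per survey: day, month and lagged climate summaries.

    *surveys* needs columns date, year, survey_index (one row per survey).
    Columns produced: tmax_day, tmin_day, rain_day; rain_month_sum,
    soil_month_mean, solar_month_mean; dd{lag} and tmin{lag} per lag; enso
    (index of the survey month).  Zero-variance columns are flagged in
    ``attrs['constant_columns']``.
    """
    surveys = surveys.drop_duplicates(["year", "survey_index"]).sort_values(
        ["year", "survey_index"])
    clim = climate.copy()
    clim["date"] = pd.to_datetime(clim["date"])
    by_day = clim.set_index("date")
    enso_map = {(int(r.year), int(r.month)): float(r.enso)
                for r in enso.itertuples()}
    rows = []
    for r in surveys.itertuples():
        date = pd.Timestamp(r.date)
        if date not in by_day.index:
            raise ValueError(f"no climate data for survey day {date.date()}")
        day = by_day.loc[date]
        month_mask = ((by_day.index.year == date.year)
                      & (by_day.index.month == date.month))
        month = by_day.loc[month_mask]
        key = (date.year, date.month)
        if key not in enso_map:
            raise ValueError(f"no ENSO value for survey month {key}")
        row = {
            "year": int(r.year), "survey_index": int(r.survey_index),
            "date": date,
            "tmax_day": float(day["tmax"]),
            "tmin_day": float(day["tmin"]),
            "rain_day": float(day["rainfall"]),
            "rain_month_sum": float(month["rainfall"].sum()),
            "soil_month_mean": float(month["soil_humidity"].mean()),
            "solar_month_mean": float(month["solar_rad"].mean()),
            "enso": enso_map[key],
        }
        for lag in lags:
            win = _window(clim, date, lag)
            daily_mean = (win["tmax"] + win["tmin"]) / 2.0
            row[f"dd{lag}"] = float(np.maximum(0.0, daily_mean - base_temp).sum())
            row[f"tmin{lag}"] = float(win["tmin"].mean())
        rows.append(row)
    out = pd.DataFrame(rows).reset_index(drop=True)
    value_cols = [c for c in out.columns
                  if c not in ("year", "survey_index", "date")]
    constant = [c for c in value_cols if out[c].nunique() <= 1]
    if constant:
        warnings.warn(f"zero-variance covariate column(s): {constant}")
    out.attrs["constant_columns"] = constant
    return out


@dataclasses.dataclass
class RegressionResult:
    """Stepwise multiple-regression outcome for one abundance series."""

    selected: list
    coefficients: dict            # predictor -> raw coefficient
    std_coefficients: dict        # predictor -> standardized coefficient
    intercept: float
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_df: tuple
    p_value: float
    dropped_collinear: list
    n_obs: int
    aic: float

    def summary(self) -> str:
        lines = [f"Stepwise regression (n={self.n_obs}): "
                 f"R2={self.r_squared:.3f} adjR2={self.adj_r_squared:.3f} "
                 f"F{self.f_df}={self.f_statistic:.3f} p={self.p_value:.4f}"]
        lines.append(f"  intercept: {self.intercept:.4f}")
        for name in self.selected:
            lines.append(f"  {name}: {self.coefficients[name]:+.4f} "
                         f"(std {self.std_coefficients[name]:+.3f})")
        if self.dropped_collinear:
            lines.append(f"  dropped for collinearity: {self.dropped_collinear}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def regression_stats(r2: float, n: int, k: int) -> tuple[float, float, float]:
    """Exact (adj R^2, F, p) identities for an OLS fit with k predictors."""
    if k == 0:
        return float("nan"), float("nan"), float("nan")
    dfe = n - k - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / dfe
    f = (r2 / k) / ((1.0 - r2) / dfe)
    p = float(stats.f.sf(f, k, dfe))
    return float(adj), float(f), p


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least squares with intercept; returns (coef incl. intercept, rss, aic)."""
    n = y.size
    Xd = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    rss = float(resid @ resid)
    k = Xd.shape[1]
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)
    return coef, rss, aic


def _tolerances(X: pd.DataFrame) -> pd.Series:
    """Tolerance 1 - R^2_j of each predictor against all the others."""
    tols = {}
    arr = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        yj = arr[:, j]
        ssy = float(((yj - yj.mean()) ** 2).sum())
        if ssy == 0:
            tols[name] = 0.0
            continue
        if others.shape[1] == 0:
            tols[name] = 1.0
            continue
        _, rss, _ = _ols(yj, others)
        tols[name] = max(0.0, rss / ssy)
    return pd.Series(tols)


def stepwise_regress(y, covariates: pd.DataFrame,
                     tolerance_threshold: float = 1e-3,
                     candidates: list | None = None) -> RegressionResult:
    """Collinearity screen + bidirectional stepwise AIC selection.

    Predictors whose tolerance (1 - R^2 against the other predictors) falls
    below *tolerance_threshold* are removed first, worst offender at a
    time, so near-duplicate climate summaries cannot enter together.
    Selection then starts from the intercept-only model, adding or removing
    one predictor per step while AIC improves.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    meta = {"year", "survey_index", "date"}
    if candidates is None:
        candidates = [c for c in covariates.columns if c not in meta]
    X = covariates[candidates].astype(float).copy()
    X = X.loc[:, X.nunique() > 1]     # constants can never be selected
    if len(X) != y.size:
        raise ValueError("response and covariates have different lengths")

    dropped = []
    while X.shape[1] >= 2:
        tols = _tolerances(X)
        worst = tols.idxmin()
        if tols[worst] >= tolerance_threshold:
            break
        dropped.append(worst)
        X = X.drop(columns=[worst])

    max_k = max(1, y.size - 2)        # keep at least 1 residual df
    selected: list = []
    _, _, current_aic = _ols(y, np.empty((y.size, 0)))
    improved = True
    while improved:
        improved = False
        moves = []
        for name in X.columns:
            if name in selected or len(selected) >= max_k:
                continue
            trial = selected + [name]
            _, _, aic = _ols(y, X[trial].to_numpy())
            moves.append((aic, "add", name))
        for name in selected:
            trial = [s for s in selected if s != name]
            _, _, aic = _ols(y, X[trial].to_numpy())
            moves.append((aic, "drop", name))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[2]))
        aic, action, name = moves[0]
        if aic < current_aic - 1e-9:
            current_aic = aic
            if action == "add":
                selected.append(name)
            else:
                selected.remove(name)
            improved = True

    selected = sorted(selected, key=list(X.columns).index)
    Xs = X[selected].to_numpy() if selected else np.empty((y.size, 0))
    coef, rss, aic = _ols(y, Xs)
    ssy = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / ssy
    k = len(selected)
    adj, f, p = regression_stats(r2, y.size, k)
    sd_y = y.std(ddof=1)
    std_coefs = {}
    for i, name in enumerate(selected):
        sd_x = X[name].std(ddof=1)
        std_coefs[name] = float(coef[i + 1] * sd_x / sd_y)
    return RegressionResult(
        selected=selected,
        coefficients={n_: float(c) for n_, c in zip(selected, coef[1:])},
        std_coefficients=std_coefs,
        intercept=float(coef[0]),
        r_squared=float(r2), adj_r_squared=adj, f_statistic=f,
        f_df=(k, y.size - k - 1), p_value=p,
        dropped_collinear=dropped, n_obs=int(y.size), aic=float(aic))
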