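"""Log-linear Poisson site-by-year trend models for monitoring counts.

This is a reimplementation of the TRIM model family used for wildlife
monitoring indices.  Counts f_ij of a species (or group) at site i in year
j are modelled with a log link:

    model 1 (no time effects):   ln mu_ij = alpha_i
    model 2 (linear trend):      ln mu_ij = alpha_i + beta * (j - 1)
    model 3 (time effects):      ln mu_ij = alpha_i + gamma_j,  gamma_1 = 0

fitted by Poisson maximum likelihood over the observed cells only (missing
site-years contribute nothing; their fitted values are model-based, which
is how indices cope with holes in the design).  Overdispersion is estimated
as sigma^2 = X^2/df (floored at 1) and inflates all parameter standard
errors by its square root.  Goodness of fit is reported through Pearson X^2
and deviance G^2 with chi-square p-values, and models are compared on the
TRIM AIC convention AIC = G^2 - 2 df (negative for well-fitting models).

From models 2 and 3 an overall multiplicative slope m — the average yearly
rate of change of the population index, m = 1.05 meaning +5% a year — is
derived with a delta-method standard error, and (m, SE) is mapped to the
standard trend categories (strong/moderate increase, stable, uncertain,
moderate/steep decline) via the 95% confidence interval against the 0.95
and 1.05 thresholds.

The entry points mirror statsmodels: ``TrimModel(matrix, model=2).fit()``
returns a ``TrimResults`` with parameters, covariance, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnualSiteMatrix

__all__ = ["TrimModel", "TrimResults", "fit_trim",
           "overall_multiplicative_slope", "classify_trend", "select_model",
           "NonConvergenceError"]

MODEL_NAMES = {1: "no time effects", 2: "linear trend", 3: "time effects"}


class NonConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message}; deviance trace: {trace}")
        self.trace = trace


def _as_matrix(matrix) -> tuple[np.ndarray, np.ndarray, list, list, str]:
    if isinstance(matrix, AnnualSiteMatrix):
        y = matrix.counts.to_numpy(dtype=float)
        obs = matrix.observed_mask.to_numpy(dtype=bool) & np.isfinite(y)
        return y, obs, matrix.sites, matrix.years, matrix.species_id
    if isinstance(matrix, pd.DataFrame):
        y = matrix.to_numpy(dtype=float)
        sites, years = list(matrix.index), list(matrix.columns)
    else:
        y = np.asarray(matrix, dtype=float)
        sites = [f"site{i + 1}" for i in range(y.shape[0])]
        years = list(range(1, y.shape[1] + 1))
    return y, np.isfinite(y), sites, years, ""


class TrimModel:
    """One of the three site-by-year log-linear Poisson models.

    Parameters
    ----------
    matrix : AnnualSiteMatrix, DataFrame or 2-D array
        Annual counts, sites in rows and years in columns.  NaN cells (or
        an explicit observed mask) are treated as unobserved.
    model : {1, 2, 3}
        1 site effects only, 2 site effects plus log-linear trend,
        3 site effects plus a free effect per year (first year reference).
    """

    def __init__(self, matrix, model: int = 2):
        if model not in (1, 2, 3):
            raise ValueError("model must be 1, 2 or 3")
        y, obs, sites, years, species = _as_matrix(matrix)
        if (np.nan_to_num(y) < 0).any():
            raise ValueError("counts must be non-negative")
        # sites with no observed or all-zero cells cannot support a log-scale
        # intercept; drop them with a warning (TRIM behaves likewise)
        site_tot = np.where(obs, y, 0.0).sum(axis=1)
        site_nobs = obs.sum(axis=1)
        keep = (site_tot > 0) & (site_nobs > 0)
        if not keep.all():
            dropped = [s for s, k in zip(sites, keep) if not k]
            warnings.warn(f"dropping site(s) with no positive counts: {dropped}")
        if keep.sum() == 0:
            raise ValueError("no sites with positive counts")
        self.model = model
        self.y = y[keep]
        self.observed = obs[keep]
        self.sites = [s for s, k in zip(sites, keep) if k]
        self.years = years
        self.species_id = species
        self.n_sites = len(self.sites)
        self.n_years = len(years)
        if model >= 2 and self.n_years < 2:
            raise ValueError("time models need at least 2 years")
        col_obs = self.observed.sum(axis=0)
        if model == 3 and (col_obs == 0).any():
            raise ValueError("model 3 needs every year observed at least once")

    # -- design ------------------------------------------------------------
    def _design(self) -> tuple[np.ndarray, np.ndarray]:
        I, J = self.n_sites, self.n_years
        rows_i, rows_j = np.nonzero(self.observed)
        n = rows_i.size
        p_time = {1: 0, 2: 1, 3: J - 1}[self.model]
        X = np.zeros((n, I + p_time))
        X[np.arange(n), rows_i] = 1.0
        if self.model == 2:
            X[:, I] = rows_j            # (j - 1) with j 1-based
        elif self.model == 3:
            for jj in range(1, J):
                X[rows_j == jj, I + jj - 1] = 1.0
        return X, self.y[self.observed]

    def fit(self, maxiter: int = 200, tol: float = 1e-12) -> "TrimResults":
        """Poisson IRLS over observed cells; raises on non-convergence."""
        X, y = self._design()
        n, p = X.shape
        beta = np.zeros(p)
        site_means = np.array([
            max(self.y[i, self.observed[i]].mean(), 0.1)
            for i in range(self.n_sites)])
        beta[:self.n_sites] = np.log(site_means)
        trace: list[float] = []
        dev_prev = np.inf
        for _ in range(maxiter):
            eta = X @ beta
            mu = np.exp(np.clip(eta, -30, 30))
            W = mu
            z = eta + (y - mu) / mu
            XtW = X.T * W
            A = XtW @ X
            b = XtW @ z
            try:
                beta_new = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
            beta = beta_new
            mu = np.exp(np.clip(X @ beta, -30, 30))
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(y > 0, y * np.log(y / mu), 0.0)
            dev = 2 * float((term - (y - mu)).sum())
            trace.append(dev)
            if abs(dev_prev - dev) < tol * (abs(dev) + 1):
                break
            dev_prev = dev
        else:
            raise NonConvergenceError("IRLS did not converge", trace)

        mu = np.exp(X @ beta)
        pearson = float(((y - mu) ** 2 / mu).sum())
        df = n - p
        sigma2 = max(1.0, pearson / df) if df > 0 else 1.0
        XtWX = (X.T * mu) @ X
        try:
            cov_unit = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            cov_unit = np.linalg.pinv(XtWX)
        cov = sigma2 * cov_unit

        fitted = self._fitted_matrix(beta)
        return TrimResults(model=self, params=beta, cov_params=cov,
                           deviance=dev, pearson_chi2=pearson, df_resid=df,
                           sigma2=sigma2, fitted=fitted)

    def _fitted_matrix(self, beta: np.ndarray) -> pd.DataFrame:
        I, J = self.n_sites, self.n_years
        alpha = beta[:I]
        eta = np.tile(alpha[:, None], (1, J))
        if self.model == 2:
            eta = eta + beta[I] * np.arange(J)[None, :]
        elif self.model == 3:
            gamma = np.concatenate([[0.0], beta[I:]])
            eta = eta + gamma[None, :]
        return pd.DataFrame(np.exp(eta), index=self.sites, columns=self.years)


@dataclasses.dataclass
class TrimResults:
    """Fitted TRIM model with diagnostics, slope and trend category."""

    model: TrimModel
    params: np.ndarray
    cov_params: np.ndarray
    deviance: float          # G^2
    pearson_chi2: float      # X^2
    df_resid: int
    sigma2: float
    fitted: pd.DataFrame     # includes model-based values for missing cells

    # -- parameter views ---------------------------------------------------
    @property
    def site_effects(self) -> pd.Series:
        return pd.Series(self.params[:self.model.n_sites],
                         index=self.model.sites, name="alpha")

    @property
    def slope_param(self) -> float | None:
        return float(self.params[self.model.n_sites]) if self.model.model == 2 else None

    @property
    def time_effects(self) -> pd.Series | None:
        if self.model.model != 3:
            return None
        gamma = np.concatenate([[0.0], self.params[self.model.n_sites:]])
        return pd.Series(gamma, index=self.model.years, name="gamma")

    # -- goodness of fit ---------------------------------------------------
    @property
    def gof_p(self) -> float:
        """Pearson chi-square goodness-of-fit p-value."""
        if self.df_resid <= 0:
            return float("nan")
        return float(stats.chi2.sf(self.pearson_chi2, self.df_resid))

    @property
    def deviance_p(self) -> float:
        if self.df_resid <= 0:
            return float("nan")
        return float(stats.chi2.sf(self.deviance, self.df_resid))

    @property
    def aic(self) -> float:
        """TRIM convention: residual deviance minus twice its df."""
        return float(self.deviance - 2 * self.df_resid)

    def wald_time_p(self) -> float:
        """Wald test of the time parameters (beta, or all gamma jointly)."""
        I = self.model.n_sites
        if self.model.model == 1:
            return float("nan")
        theta = self.params[I:]
        V = self.cov_params[I:, I:]
        try:
            w = float(theta @ np.linalg.solve(V, theta))
        except np.linalg.LinAlgError:
            w = float(theta @ np.linalg.pinv(V) @ theta)
        return float(stats.chi2.sf(w, theta.size))

    # -- overall multiplicative slope --------------------------------------
    def overall_slope(self) -> tuple[float, float]:
        """Multiplicative yearly slope m and its delta-method SE.

        Model 2: m = exp(beta).  Model 3: the least-squares slope b of
        ln(sum_i mu_ij) on year rank is exp-transformed; since the yearly
        total factorises as exp(gamma_j) * sum_i exp(alpha_i), b is a fixed
        linear combination of the gamma and its variance follows from their
        covariance.
        """
        I, J = self.model.n_sites, self.model.n_years
        if self.model.model == 1:
            raise ValueError("overall slope undefined for model 1")
        if self.model.model == 2:
            b = float(self.params[I])
            var_b = float(self.cov_params[I, I])
        else:
            j = np.arange(J, dtype=float)
            w = (j - j.mean()) / ((j - j.mean()) ** 2).sum()
            log_tot = np.log(self.fitted.sum(axis=0).to_numpy(dtype=float))
            b = float(w @ log_tot)
            # d log_tot_j / d gamma_k = delta_jk (j>=2); gamma_1 fixed at 0
            wg = w[1:]
            var_b = float(wg @ self.cov_params[I:, I:] @ wg)
        m = float(np.exp(b))
        return m, m * float(np.sqrt(max(var_b, 0.0)))

    @property
    def multiplicative_slope(self) -> float:
        return self.overall_slope()[0]

    @property
    def trend_category(self) -> str:
        try:
            m, se = self.overall_slope()
        except ValueError:
            return "not applicable"
        return classify_trend(m, se)

    def plot(self, ax=None):
        """Observed vs fitted yearly index (summed over sites)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        years = self.model.years
        observed = np.where(self.model.observed, self.model.y, np.nan)
        ax.plot(years, np.nansum(observed, axis=0), "o", color="0.4",
                label="observed total")
        ax.plot(years, self.fitted.sum(axis=0), "-", color="k",
                label=f"model {self.model.model} fit")
        ax.set_xlabel("year")
        ax.set_ylabel("summed count")
        if self.model.species_id:
            ax.set_title(self.model.species_id)
        ax.legend()
        return ax

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"TRIM model {self.model.model} ({MODEL_NAMES[self.model.model]})"
            + (f" — {self.model.species_id}" if self.model.species_id else ""),
            f"  sites: {self.model.n_sites}  years: {self.model.n_years}  "
            f"observed cells: {int(self.model.observed.sum())}",
            f"  deviance G2 = {self.deviance:.4f}  Pearson X2 = "
            f"{self.pearson_chi2:.4f}  df = {self.df_resid}",
            f"  GOF p (X2) = {self.gof_p:.4f}  sigma2 = {self.sigma2:.4f}  "
            f"AIC = {self.aic:.2f}",
        ]
        if self.model.model != 1:
            m, se = self.overall_slope()
            lines.append(f"  multiplicative slope m = {m:.4f} (SE {se:.4f})"
                         f" -> {classify_trend(m, se)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "model": self.model.model,
            "model_name": MODEL_NAMES[self.model.model],
            "species": self.model.species_id,
            "site_effects": {s: float(a) for s, a in self.site_effects.items()},
            "deviance": self.deviance,
            "pearson_chi2": self.pearson_chi2,
            "df_resid": self.df_resid,
            "gof_p": self.gof_p,
            "sigma2": self.sigma2,
            "aic": self.aic,
        }
        if self.model.model != 1:
            m, se = self.overall_slope()
            out.update({"multiplicative_slope": m, "slope_se": se,
                        "trend_category": classify_trend(m, se)})
        if self.model.model == 3:
            out["time_effects"] = {str(y): float(g)
                                   for y, g in self.time_effects.items()}
        return out


def fit_trim(matrix, model: int = 2, **kwargs) -> TrimResults:
    """Convenience wrapper: ``TrimModel(matrix, model).fit()``."""
    return TrimModel(matrix, model=model).fit(**kwargs)


def overall_multiplicative_slope(fit: TrimResults) -> tuple[float, float]:
    """Overall multiplicative yearly slope (m, SE) of a fitted model 2 or 3."""
    return fit.overall_slope()


def classify_trend(m: float, se: float) -> str:
    """Map a multiplicative slope and its SE to a TRIM trend category.

    The 95% Wald interval m +/- 1.96 SE is held against 1 (no change) and
    the +/-5%-per-year thresholds 0.95 and 1.05:

    - lower bound > 1.05          -> "strong increase"
    - 1 < lower bound <= 1.05     -> "moderate increase"
    - upper bound < 0.95          -> "steep decline"
    - 0.95 <= upper bound < 1     -> "moderate decline"
    - interval inside [0.95,1.05] -> "stable"
    - anything else               -> "uncertain"
    """
    if m <= 0 or se < 0 or not (np.isfinite(m) and np.isfinite(se)):
        raise ValueError("need m > 0 and SE >= 0")
    lo, hi = m - 1.96 * se, m + 1.96 * se
    if lo > 1.05:
        return "strong increase"
    if lo > 1.0:
        return "moderate increase"
    if hi < 0.95:
        return "steep decline"
    if hi < 1.0:
        return "moderate decline"
    if lo >= 0.95 and hi <= 1.05:
        return "stable"
    return "uncertain"


def select_model(fits, gof_alpha: float = 0.01,
                 wald_alpha: float = 0.05) -> tuple[TrimResults, bool]:
    """Pick the lowest-AIC fit; flag when no candidate is adequate.

    Returns ``(best, none_significant)`` where the flag is raised when
    every candidate's goodness-of-fit p falls below *gof_alpha* and no
    Wald test on time parameters reaches *wald_alpha* — the situation a
    monitoring report writes up as "none of models significant".
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no candidate fits")
    best = min(fits, key=lambda f: f.aic)
    if len(fits) == 1:
        return best, False
    all_bad_fit = all(np.nan_to_num(f.gof_p, nan=1.0) < gof_alpha for f in fits)
    any_time_signal = any(
        np.nan_to_num(f.wald_time_p(), nan=1.0) <= wald_alpha for f in fits)
    return best, bool(all_bad_fit and not any_time_signal)
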