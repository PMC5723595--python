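"""Study-scale validation experiments for the analysis chain.

Each function here re-runs one part of the package under the conditions of
the motivating monitoring design (10 light-trap sites, 8 years, 4 surveys a
year) and returns the measured operating characteristics: trend-parameter
recovery and confidence-interval coverage, coherence of the model family,
calibration and power of the phylogenetic-clustering test, predictor
recovery of the stepwise climate regressions, and seasonal forecast
accuracy.  They back both the acceptance test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .climate import regression_stats, stepwise_regress
from .forecast import forecast_seasonal
from .io import read_newick
from .phylo import mpd_permutation_test, patristic_matrix
from .simulate import simulate_tree_and_traits
from .trend import classify_trend, fit_trim

__all__ = [
    "TREND_CLASSIFICATION_EXAMPLE", "NONSTANDARD_EXAMPLE_ROW",
    "trend_classification_concordance", "trim_parameter_recovery",
    "model_family_coherence", "mpd_null_calibration", "mpd_clade_power",
    "stepwise_selection_power", "forecast_cosine_check", "adj_r2_from_f",
]

#: Published saturniid monitoring results used as a worked classification
#: example: (series, multiplicative slope, SE, printed category).  The 13
#: rows follow the standard TRIM categorisation rule exactly.
TREND_CLASSIFICATION_EXAMPLE = [
    ("Oxyteninae", 1.041, 0.058, "uncertain"),
    ("functional cluster 2", 1.030, 0.0415, "uncertain"),
    ("functional cluster 5", 1.091, 0.032, "moderate increase"),
    ("Hylesia praedpichinchensis", 1.189, 0.066, "strong increase"),
    ("Automeris parapichinchensis", 1.017, 0.052, "uncertain"),
    ("Automeris vanschaycki", 1.159, 0.059, "moderate increase"),
    ("Periphoba sp. 1YB", 0.962, 0.059, "uncertain"),
    ("Automeris fieldi", 1.190, 0.176, "uncertain"),
    ("Pseudodirphia eupanamensis", 1.022, 0.082, "uncertain"),
    ("Oxytenis naemia", 0.896, 0.127, "uncertain"),
    ("Automeris belti", 0.999, 0.085, "uncertain"),
    ("Caio championi", 1.085, 0.109, "uncertain"),
    ("Oxytenis beprea", 0.998, 0.111, "uncertain"),
]

#: One published row whose printed category ("uncertain") deviates from the
#: standard rule (its 95% CI sits wholly above 1.05); kept out of the
#: concordance example and flagged rather than emulated.
NONSTANDARD_EXAMPLE_ROW = ("Rhescyntis hippodamia", 1.301, 0.055, "uncertain")


def trend_classification_concordance() -> dict:
    """Fraction of the worked example reproduced by ``classify_trend``."""
    hits = sum(classify_trend(m, se) == category
               for _, m, se, category in TREND_CLASSIFICATION_EXAMPLE)
    n = len(TREND_CLASSIFICATION_EXAMPLE)
    return {"concordant": hits, "n": n, "fraction": hits / n}


def trim_parameter_recovery(n_reps: int = 200, true_m: float = 1.10,
                            n_sites: int = 10, n_years: int = 8,
                            base_mean: float = 10.0, seed: int = 0) -> dict:
    """Recovery of the multiplicative slope from Poisson site x year data."""
    rng = np.random.default_rng(seed)
    years = np.arange(n_years)
    m_hats = np.empty(n_reps)
    covered = 0
    for r in range(n_reps):
        mu = base_mean * true_m ** years[None, :] * np.ones((n_sites, 1))
        mat = rng.poisson(mu).astype(float)
        res = fit_trim(mat, model=2)
        m, se = res.overall_slope()
        m_hats[r] = m
        covered += abs(m - true_m) <= 1.96 * se
    return {"mean_m": float(m_hats.mean()), "sd_m": float(m_hats.std(ddof=1)),
            "coverage": covered / n_reps, "n_reps": n_reps,
            "true_m": true_m}


def model_family_coherence(n_matrices: int = 50, seed: int = 0) -> dict:
    """Deviance nesting G2(1) >= G2(2) >= G2(3) and the J=2 equivalence of
    the linear-trend and time-effects models, over random count matrices."""
    rng = np.random.default_rng(seed)
    worst_nesting = 0.0
    for _ in range(n_matrices):
        shape = (int(rng.integers(3, 8)), int(rng.integers(3, 8)))
        mat = rng.poisson(rng.uniform(3, 25), size=shape).astype(float) + 1.0
        g = [fit_trim(mat, model=k).deviance for k in (1, 2, 3)]
        worst_nesting = max(worst_nesting, g[1] - g[0], g[2] - g[1])
    worst_j2 = 0.0
    for _ in range(n_matrices):
        mat = rng.poisson(rng.uniform(3, 25),
                          size=(int(rng.integers(2, 8)), 2)).astype(float) + 1.0
        m2 = fit_trim(mat, model=2).overall_slope()[0]
        m3 = fit_trim(mat, model=3).overall_slope()[0]
        worst_j2 = max(worst_j2, abs(m2 - m3))
    return {"max_nesting_violation": worst_nesting,
            "max_j2_slope_gap": worst_j2, "n_matrices": n_matrices}


def mpd_null_calibration(n_trials: int = 1000, n_tips: int = 64,
                         group_size: int = 8, n_perm: int = 999,
                         alpha: float = 0.05, seed: int = 0,
                         trials_per_tree: int = 40) -> dict:
    """Type-I error of the MPD permutation test for random tip groups."""
    rng = np.random.default_rng(seed)
    rejections = 0
    done = 0
    tree_seed = 0
    while done < n_trials:
        tree_seed += 1
        tree, _, _ = simulate_tree_and_traits(
            n_tips, seed=int(rng.integers(2 ** 31)))
        dist = patristic_matrix(tree)
        for _ in range(min(trials_per_tree, n_trials - done)):
            members = rng.choice(dist.index, size=group_size, replace=False)
            labels = pd.Series(1, index=members)
            res = mpd_permutation_test(dist, labels, n_perm=n_perm,
                                       seed=int(rng.integers(2 ** 31)))
            rejections += res[1].p_value <= alpha
            done += 1
    return {"rejection_rate": rejections / n_trials, "n_trials": n_trials,
            "alpha": alpha}


def _depth_separated_tree(depth: int = 6, short: float = 0.05,
                          long: float = 1.0) -> str:
    """Balanced binary newick whose first 8-tip clade is internally short."""
    def build(d, prefix):
        bl = short if prefix.startswith("000") and len(prefix) >= 3 else long
        if d == 0:
            return f"t{prefix}:{bl}"
        return f"({build(d - 1, prefix + '0')},{build(d - 1, prefix + '1')}):{bl}"
    return build(depth, "") + ";"


def mpd_clade_power(n_seeds: int = 100, n_perm: int = 999,
                    alpha: float = 0.01, seed: int = 0) -> dict:
    """Rejection frequency for a genuinely clustered (clade) group."""
    tree = read_newick(_depth_separated_tree())
    dist = patristic_matrix(tree)
    clade = [t for t in dist.index if t.startswith("t000")]
    labels = pd.Series(2, index=dist.index)
    labels.loc[clade] = 1
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        res = mpd_permutation_test(dist, labels, n_perm=n_perm,
                                   seed=int(rng.integers(2 ** 31)))
        hits += res[1].p_value <= alpha
    return {"power": hits / n_seeds, "n_seeds": n_seeds, "alpha": alpha}


def stepwise_selection_power(n_reps: int = 100, n_obs: int = 32,
                             n_true: int = 3, n_noise: int = 7,
                             effect_sd: float = 1.0, seed: int = 0) -> dict:
    """Recovery of true predictors among noise in stepwise AIC selection."""
    rng = np.random.default_rng(seed)
    all_true = 0
    false_counts = []
    true_names = [f"true{j}" for j in range(n_true)]
    noise_names = [f"noise{j}" for j in range(n_noise)]
    for _ in range(n_reps):
        X = pd.DataFrame(rng.normal(size=(n_obs, n_true + n_noise)),
                         columns=true_names + noise_names)
        y = X[true_names].sum(axis=1) * effect_sd + rng.normal(size=n_obs)
        res = stepwise_regress(y.to_numpy(), X)
        chosen = set(res.selected)
        all_true += set(true_names) <= chosen
        false_counts.append(len(chosen - set(true_names)))
    return {"all_true_rate": all_true / n_reps,
            "mean_false_inclusions": float(np.mean(false_counts)),
            "n_reps": n_reps}


def forecast_cosine_check(n_points: int = 32, amplitude: float = 5.0,
                          horizon: int = 8) -> dict:
    """Forecast error on a noiseless period-4 cosine, relative to amplitude^2."""
    t = np.arange(n_points)
    y = amplitude * np.cos(2 * np.pi * t / 4) + 2 * amplitude
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = forecast_seasonal(y, horizon=horizon)
    t_fut = np.arange(n_points, n_points + horizon)
    truth = amplitude * np.cos(2 * np.pi * t_fut / 4) + 2 * amplitude
    mse = float(np.mean((res.forecast - truth) ** 2))
    return {"mse": mse, "mse_over_amp2": mse / amplitude ** 2,
            "horizon": res.horizon}


def adj_r2_from_f(f: float, n: int, k: int) -> dict:
    """Invert the exact F identity to (R^2, adjusted R^2) for an OLS fit.

    F = (R^2/k)/((1-R^2)/(n-k-1)) gives R^2 = Fk/(Fk + n-k-1); the adjusted
    value then follows from the usual small-sample correction.  Used to
    check internal consistency of reported regression summaries.
    """
    dfe = n - k - 1
    r2 = f * k / (f * k + dfe)
    adj, f_back, p = regression_stats(r2, n, k)
    return {"r_squared": float(r2), "adj_r_squared": adj,
            "f_statistic": f_back, "p_value": p, "n": n, "k": k}
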