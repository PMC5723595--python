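"""Richness estimation, assemblage similarity, accumulation curves, ordination.

Covers the assemblage-level toolkit of a light-trap monitoring programme:
the incidence-based coverage richness estimator (ICE), randomized species
accumulation curves, saturating curve fits for cryptic-species discovery,
the Morisita-Horn abundance similarity, nonmetric multidimensional scaling
on Bray-Curtis distances, and canonical correspondence analysis with a
permutation test for the climate-constrained fraction of compositional
inertia.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS
from skbio.stats.ordination import cca as _skbio_cca

__all__ = ["RichnessEstimate", "CurveFit", "OrdinationResult",
           "ice_estimate", "accumulation_curve", "fit_reciprocal_log",
           "morisita_horn", "nmds", "cca"]


# ---------------------------------------------------------------------------
# Richness


@dataclasses.dataclass
class RichnessEstimate:
    observed: int
    ice: float
    s_frequent: int
    s_infrequent: int
    q_counts: dict            # incidence frequency k -> Q_k, k = 1..cutoff
    coverage: float           # C_ice
    cv_squared: float         # gamma^2_ice
    cutoff: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def ice_estimate(incidence: pd.DataFrame | np.ndarray,
                 cutoff: int = 10) -> RichnessEstimate:
    """Incidence-based coverage estimator of species richness.

    *incidence* is species x samples (truthy = present).  Species found in
    at most *cutoff* samples are "infrequent"; sample coverage of that pool
    is C = 1 - Q1/N_infr (Q1 = species in exactly one sample, N_infr total
    infrequent incidences) and

        ICE = S_freq + S_infr / C + (Q1 / C) * gamma^2

    with the bias-corrected squared coefficient of variation gamma^2
    (floored at 0).  Undefined (raises) when every infrequent species is a
    unique, i.e. coverage is zero.
    """
    M = (np.asarray(incidence) > 0).astype(int)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need a species x samples matrix with >= 2 samples")
    freq = M.sum(axis=1)
    freq = freq[freq > 0]
    s_obs = int(freq.size)
    infreq = freq[(freq >= 1) & (freq <= cutoff)]
    s_infr = int(infreq.size)
    s_freq = s_obs - s_infr
    q = {k: int((infreq == k).sum()) for k in range(1, cutoff + 1)}
    if s_infr == 0:
        return RichnessEstimate(observed=s_obs, ice=float(s_obs),
                                s_frequent=s_freq, s_infrequent=0, q_counts=q,
                                coverage=1.0, cv_squared=0.0, cutoff=cutoff)
    n_infr = int(infreq.sum())
    q1 = q[1]
    coverage = 1.0 - q1 / n_infr
    if coverage <= 0:
        raise ValueError("ICE undefined: every infrequent species is a unique "
                         "(zero sample coverage)")
    infreq_any = (M[(M.sum(axis=1) >= 1) & (M.sum(axis=1) <= cutoff)]
                  .sum(axis=0) > 0)
    m_infr = int(infreq_any.sum())
    gamma2 = 0.0
    if m_infr > 1:
        ssum = sum(k * (k - 1) * q[k] for k in range(1, cutoff + 1))
        gamma2 = max(0.0, (s_infr / coverage) * (m_infr / (m_infr - 1))
                     * ssum / n_infr ** 2 - 1.0)
    ice = s_freq + s_infr / coverage + (q1 / coverage) * gamma2
    return RichnessEstimate(observed=s_obs, ice=float(ice), s_frequent=s_freq,
                            s_infrequent=s_infr, q_counts=q,
                            coverage=float(coverage), cv_squared=float(gamma2),
                            cutoff=cutoff)


def accumulation_curve(incidence: pd.DataFrame | np.ndarray,
                       n_rand: int = 100, seed: int | None = None
                       ) -> pd.DataFrame:
    """Randomized species accumulation: mean +/- sd richness per added sample."""
    M = (np.asarray(incidence) > 0)
    n_samples = M.shape[1]
    rng = np.random.default_rng(seed)
    curves = np.empty((n_rand, n_samples))
    for r in range(n_rand):
        order = rng.permutation(n_samples)
        seen = np.cumsum(M[:, order], axis=1) > 0
        curves[r] = seen.sum(axis=0)
    return pd.DataFrame({"samples": np.arange(1, n_samples + 1),
                         "mean_richness": curves.mean(axis=0),
                         "sd_richness": curves.std(axis=0, ddof=1)})


# ---------------------------------------------------------------------------
# Cryptic-species discovery curve


@dataclasses.dataclass
class CurveFit:
    model: str
    a: float
    b: float
    r_squared: float
    aicc: float
    comparison: list          # [(model, aicc, r2)] sorted by AICc


def _aicc(rss: float, n: int, k: int) -> float:
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


_CURVE_MODELS = {
    # name -> (function, initial-guess builder)
    "reciprocal_log": (lambda x, a, b: 1.0 / (a + b * np.log(x)),
                       lambda x, y: _init_reciprocal_log(x, y)),
    "michaelis_menten": (lambda x, a, b: a * x / (b + x),
                         lambda x, y: (max(y.max(), 1e-6) * 1.2, np.median(x))),
    "asymptotic_exp": (lambda x, a, b: a * (1 - np.exp(-b * x)),
                       lambda x, y: (max(y.max(), 1e-6) * 1.1, 1.0 / np.mean(x))),
}


def _init_reciprocal_log(x, y):
    mask = y > 0
    if mask.sum() >= 2:
        coef = np.polyfit(np.log(x[mask]), 1.0 / y[mask], 1)
        return coef[1], coef[0]
    return 1.0, -0.1


def fit_reciprocal_log(x, y) -> CurveFit:
    """Fit y = 1/(a + b ln x) and rank it by AICc against saturating rivals.

    The reciprocal-logarithm form is the conventional description of
    cryptic-species accumulation against sequencing effort; Michaelis-
    Menten and asymptotic-exponential fits are reported alongside so the
    ranking is visible.  Least squares on the original y scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 matching points")
    if not (np.diff(x) > 0).all() or (x <= 1).any():
        raise ValueError("x must be strictly increasing and > 1")
    if np.allclose(y, 0):
        raise ValueError("y is identically zero; nothing to fit")

    ssy = float(((y - y.mean()) ** 2).sum())
    results = {}
    for name, (fn, guess) in _CURVE_MODELS.items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(fn, x, y, p0=guess(x, y), maxfev=20000)
            resid = y - fn(x, *popt)
            rss = float(resid @ resid)
            r2 = 1.0 - rss / ssy if ssy > 0 else float("nan")
            results[name] = (popt, _aicc(rss, x.size, 3), r2)
        except (RuntimeError, TypeError):
            continue
    if "reciprocal_log" not in results:
        raise RuntimeError("reciprocal-logarithm fit failed")
    ranking = sorted(((nm, aicc, r2) for nm, (_, aicc, r2) in results.items()),
                     key=lambda t: t[1])
    popt, aicc, r2 = results["reciprocal_log"]
    return CurveFit(model="reciprocal_log", a=float(popt[0]), b=float(popt[1]),
                    r_squared=float(r2), aicc=float(aicc), comparison=ranking)


# ---------------------------------------------------------------------------
# Similarity


def morisita_horn(a, b) -> float:
    """Morisita-Horn abundance similarity in [0, 1].

    C = 2 sum(a_i b_i) / ((d_a + d_b) A B) with d_a = sum(a_i^2)/A^2; equal
    to 1 for proportional assemblages and 0 for disjoint ones.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    A, B = a.sum(), b.sum()
    if A <= 0 or B <= 0:
        raise ValueError("both assemblages need positive totals")
    da = (a ** 2).sum() / A ** 2
    db = (b ** 2).sum() / B ** 2
    return float(2 * (a * b).sum() / ((da + db) * A * B))


# ---------------------------------------------------------------------------
# Ordination


@dataclasses.dataclass
class OrdinationResult:
    """NMDS or CCA outcome (fields unused by the method are None)."""

    method: str
    scores: pd.DataFrame | None = None        # objects x axes
    stress: float | None = None               # NMDS Kruskal stress
    degenerate: bool = False
    constrained_fraction: float | None = None
    pseudo_f: float | None = None
    p_value: float | None = None
    dropped_covariates: list | None = None

    def axis_correlation(self, values, axis: int = 0) -> float:
        """|Pearson r| between an axis and a covariate (axes have arbitrary
        sign and rotation, so only the magnitude is meaningful)."""
        v = np.asarray(values, dtype=float)
        s = self.scores.iloc[:, axis].to_numpy()
        return float(abs(np.corrcoef(s, v)[0, 1]))


def nmds(community: pd.DataFrame | np.ndarray, n_dims: int = 2,
         seed: int | None = None, n_init: int = 16,
         max_iter: int = 500) -> OrdinationResult:
    """Nonmetric MDS of a samples x species abundance matrix (Bray-Curtis).

    Runs several random starts and keeps the lowest-stress configuration;
    stress is Kruskal stress-1.  Identical rows (zero distances) are
    flagged degenerate.
    """
    comm = community if isinstance(community, pd.DataFrame) else pd.DataFrame(community)
    X = comm.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 objects")
    D = squareform(pdist(X, metric="braycurtis"))
    off = D[np.triu_indices_from(D, k=1)]
    degenerate = bool(np.any(off == 0))
    if degenerate:
        warnings.warn("identical rows give zero Bray-Curtis distances; "
                      "NMDS configuration is degenerate")
    # classical-scaling start (the usual metaMDS strategy) plus random
    # restarts; keep the lowest-stress configuration
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:n_dims]
    pcoa_init = evecs[:, idx] * np.sqrt(np.clip(evals[idx], 0, None))

    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    inits = [pcoa_init] + [rng.normal(size=(n, n_dims))
                           for _ in range(max(0, n_init - 1))]
    for init in inits:
        mds = MDS(n_components=n_dims, metric_mds=False, metric="precomputed",
                  n_init=1, init="random", max_iter=max_iter,
                  random_state=int(rng.integers(2 ** 31)),
                  normalized_stress=True)
        coords = mds.fit_transform(D, init=init)
        if mds.stress_ < best_stress:
            best_coords, best_stress = coords, float(mds.stress_)
    # rotate to principal axes so axis 1 carries the dominant variation
    centred = best_coords - best_coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    rotated = centred @ vt.T
    scores = pd.DataFrame(rotated, index=comm.index,
                          columns=[f"NMDS{k + 1}" for k in range(n_dims)])
    return OrdinationResult(method="nmds", scores=scores,
                            stress=best_stress, degenerate=degenerate)


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Greedily drop covariate columns until the centred matrix is full rank."""
    dropped = []
    X = X.loc[:, X.nunique() > 1].copy()
    while X.shape[1] > 0:
        arr = X.to_numpy(dtype=float)
        arr = (arr - arr.mean(axis=0)) / arr.std(axis=0, ddof=0)
        if np.linalg.matrix_rank(arr, tol=1e-8) == X.shape[1]:
            break
        dropped.append(X.columns[-1])
        X = X.iloc[:, :-1]
    return X, dropped


def cca(community: pd.DataFrame, covariates: pd.DataFrame,
        n_perm: int = 999, seed: int | None = None) -> OrdinationResult:
    """Canonical correspondence analysis with a global permutation test.

    Reports the fraction of total compositional inertia captured by the
    constrained axes, the pseudo-F, and a p-value from *n_perm* row
    permutations of the covariate table.
    """
    comm = community.astype(float)
    comm = comm.loc[comm.sum(axis=1) > 0, comm.sum(axis=0) > 0]
    X = covariates.loc[comm.index].astype(float)
    X, dropped = _drop_collinear(X)
    if dropped:
        warnings.warn(f"dropping collinear covariate column(s): {list(dropped)}")
    if X.shape[1] == 0:
        raise ValueError("no usable covariates after collinearity screen")
    n, q = X.shape

    def _fraction(xmat: pd.DataFrame) -> tuple[float, float]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _skbio_cca(comm, xmat)
        props = res.proportion_explained.to_numpy()
        constrained = float(props[:q].sum())
        resid = max(1e-12, 1.0 - constrained)
        dfe = n - 1 - q
        f = (constrained / q) / (resid / dfe) if dfe > 0 else float("nan")
        return constrained, f

    frac_obs, f_obs = _fraction(X)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Xp = pd.DataFrame(X.to_numpy()[perm], index=X.index, columns=X.columns)
        _, f_p = _fraction(Xp)
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return OrdinationResult(method="cca", constrained_fraction=frac_obs,
                            pseudo_f=f_obs, p_value=float(p),
                            dropped_covariates=list(dropped))
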