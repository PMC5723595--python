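"""Synthetic light-trap monitoring bundles: counts, traits, trees, climate.

The generator emulates the structure of a tropical moth monitoring design —
I sites sampled four times a year over J years — with species-specific site
effects, multiplicative annual trends, seasonal peaks on the four-survey
cycle, ENSO sensitivity, and optional anomaly years, so that every analysis
stage can be exercised without any field data.

Expected counts follow

    ln mu_{s,i,j,t} = a_si + ln(m_s) (j-1) + kappa_s cos(2 pi (t - phi_s)/4)
                      + e_s ENSO_j + anomaly_j

with counts drawn Poisson(mu) or negative-binomial(mu, theta).
"""

from __future__ import annotations

import dataclasses
import random
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io import DEFAULT_ANCHOR_MONTHS, RECORD_COLUMNS

__all__ = [
    "SimulationSpec", "simulate_counts", "simulate_tree_and_traits",
    "simulate_climate", "simulate_bundle",
]


def _species_ids(n: int) -> list[str]:
    return [f"sp{i + 1:03d}" for i in range(n)]


@dataclasses.dataclass
class SimulationSpec:
    """Parameters of a synthetic monitoring study.

    Per-species arrays may be scalars (broadcast to all species).  ``theta``
    is the negative-binomial shape; ``None`` draws Poisson counts.  ``enso``
    is a per-year index series fed to species through their sensitivities;
    ``anomaly_years`` maps year offsets (0-based) to log-scale multipliers
    applied to every species, emulating outbreak years.
    """

    n_sites: int = 10
    n_years: int = 8
    n_species: int = 20
    base_log_abundance: float | np.ndarray = np.log(10.0)
    site_effect_sd: float = 0.3
    trend: float | np.ndarray = 1.0          # multiplicative yearly slope m_s
    seasonality: float | np.ndarray | None = None   # kappa_s; None = varied
    peak_survey: int | np.ndarray | None = None     # phi_s in 1..4; None = varied
    enso_sensitivity: float | np.ndarray | None = None  # e_s; None = varied
    enso: np.ndarray | None = None           # per-year index, default zeros
    theta: float | None = 5.0                # NB shape; None = Poisson
    anomaly_years: Mapping[int, float] = dataclasses.field(default_factory=dict)
    start_year: int = 2009
    seed: int = 0

    def __post_init__(self):
        if min(self.n_sites, self.n_years, self.n_species) < 1:
            raise ValueError("n_sites, n_years, n_species must all be >= 1")
        # default community: a spread of seasonal strengths, staggered peak
        # surveys and mixed climate sensitivity, so derived traits (Var_Peak,
        # ENSO response) vary across species instead of collapsing
        s = np.arange(self.n_species)
        if self.seasonality is None:
            self.seasonality = np.array([0.2, 0.6, 1.0, 1.6])[s % 4]
        if self.peak_survey is None:
            self.peak_survey = 1 + (s // 4) % 4
        if self.enso_sensitivity is None:
            self.enso_sensitivity = np.array([0.0, 0.25, 0.5])[s % 3]
        if np.any(np.asarray(self.trend, dtype=float) <= 0):
            raise ValueError("trend multipliers m_s must be positive")
        if np.any(np.asarray(self.seasonality, dtype=float) < 0):
            raise ValueError("seasonality kappa_s must be >= 0")
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive (or None for Poisson)")
        phi = np.asarray(self.peak_survey)
        if not np.isin(phi, [1, 2, 3, 4]).all():
            raise ValueError("peak_survey must be in {1,2,3,4}")

    def _per_species(self, value) -> np.ndarray:
        return np.broadcast_to(np.asarray(value, dtype=float),
                               (self.n_species,)).copy()


def _survey_dates(spec: SimulationSpec) -> pd.DataFrame:
    rows = []
    for j in range(spec.n_years):
        year = spec.start_year + j
        for t, month in enumerate(DEFAULT_ANCHOR_MONTHS, start=1):
            rows.append({"year": year, "survey_index": t,
                         "date": pd.Timestamp(year=year, month=month, day=15)})
    return pd.DataFrame(rows)


def simulate_counts(spec: SimulationSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a full set of survey records from the model above.

    Returns a record frame (``site_id, date, year, survey_index, species_id,
    count``) including explicit zero rows, so the observed mask is complete.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    S, I, J = spec.n_species, spec.n_sites, spec.n_years
    base = spec._per_species(spec.base_log_abundance)
    m = spec._per_species(spec.trend)
    kappa = spec._per_species(spec.seasonality)
    phi = np.broadcast_to(np.asarray(spec.peak_survey), (S,)).astype(float)
    esens = spec._per_species(spec.enso_sensitivity)
    enso = (np.zeros(J) if spec.enso is None
            else np.asarray(spec.enso, dtype=float))
    if enso.shape != (J,):
        raise ValueError("enso must have one value per year")
    anomaly = np.zeros(J)
    for j, mult in spec.anomaly_years.items():
        if mult <= 0:
            raise ValueError("anomaly multipliers must be positive")
        anomaly[int(j)] = np.log(float(mult))

    site_fx = rng.normal(0.0, spec.site_effect_sd, size=(S, I))
    a = base[:, None] + site_fx                       # a_si
    years = np.arange(J)
    surveys = np.arange(1, 5)
    season = kappa[:, None] * np.cos(2 * np.pi * (surveys[None, :] - phi[:, None]) / 4)
    log_mu = (a[:, :, None, None]
              + np.log(m)[:, None, None, None] * years[None, None, :, None]
              + season[:, None, None, :]
              + (esens[:, None] * enso[None, :])[:, None, :, None]
              + anomaly[None, None, :, None])
    mu = np.exp(log_mu)                               # S x I x J x 4
    if spec.theta is None:
        counts = rng.poisson(mu)
    else:
        p = spec.theta / (spec.theta + mu)
        counts = rng.negative_binomial(spec.theta, p)

    species = _species_ids(S)
    sites = [f"site{i + 1:02d}" for i in range(I)]
    cal = _survey_dates(spec)
    date_lookup = {(r.year, r.survey_index): r.date for r in cal.itertuples()}
    s_idx, i_idx, j_idx, t_idx = np.meshgrid(
        np.arange(S), np.arange(I), years, surveys, indexing="ij")
    frame = pd.DataFrame({
        "site_id": np.asarray(sites)[i_idx.ravel()],
        "year": spec.start_year + j_idx.ravel(),
        "survey_index": t_idx.ravel(),
        "species_id": np.asarray(species)[s_idx.ravel()],
        "count": counts.ravel().astype(np.int64),
    })
    frame["date"] = [date_lookup[(y, t)] for y, t in
                     zip(frame["year"], frame["survey_index"])]
    return frame[RECORD_COLUMNS].sort_values(
        ["site_id", "year", "survey_index", "species_id"]).reset_index(drop=True)


def _brownian_tips(tree: dendropy.Tree, rate: float,
                   rng: np.random.Generator) -> dict[str, float]:
    """One Brownian-motion realisation along the tree; returns tip values."""
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[id(node.parent_node)]
        bl = node.edge.length or 0.0
        values[id(node)] = parent + rng.normal(0.0, np.sqrt(rate * bl) if bl > 0 else 0.0)
    return {leaf.taxon.label: values[id(leaf)]
            for leaf in tree.leaf_node_iter()}


def simulate_tree_and_traits(n_species: int, signal: float | None = 1.0,
                             seed: int = 0, n_families: int = 50,
                             ) -> tuple[dendropy.Tree, pd.DataFrame, pd.DataFrame]:
    """Simulate a Yule tree plus wing measurements and host-plant records.

    With ``signal`` set, log forewing length and the log thorax/forewing
    ratio evolve by Brownian motion at that rate on the tree, so close
    relatives have similar morphology; with ``signal=None`` traits are
    independent draws.  Host families are drawn per species with a
    Beta-distributed inclusion probability, giving a spread of diet
    breadths from specialist to generalist.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species,
        rng=random.Random(int(rng.integers(2 ** 31))))
    ids = _species_ids(n_species)
    for label, leaf in zip(ids, tree.leaf_node_iter()):
        leaf.taxon.label = label
    # rescale to unit depth so Brownian rates are comparable across sizes
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    if depth > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length:
                edge.length /= depth

    if signal is not None:
        z_fw = _brownian_tips(tree, signal, rng)
        z_ratio = _brownian_tips(tree, signal, rng)
        z1 = np.array([z_fw[s] for s in ids])
        z2 = np.array([z_ratio[s] for s in ids])
    else:
        z1 = rng.normal(size=n_species)
        z2 = rng.normal(size=n_species)
    fw = 55.0 * np.exp(0.35 * z1)                    # forewing length, mm
    tw = fw * 0.18 * np.exp(0.25 * z2)               # thorax width, mm
    traits = pd.DataFrame({"species_id": ids, "FW": fw, "TW": tw})

    families = [f"fam{k + 1:02d}" for k in range(n_families)]
    rows = []
    for s in ids:
        p = rng.beta(1.2, 6.0)                       # specialisation dial
        n_use = max(1, rng.binomial(n_families, p))
        used = rng.choice(families, size=n_use, replace=False)
        rows.extend({"species_id": s, "plant_family": f} for f in sorted(used))
    hosts = pd.DataFrame(rows)
    return tree, traits, hosts


def simulate_climate(n_years: int, seed: int = 0, start_year: int = 2009,
                     noise_sd: float = 1.0, enso_phi: float = 0.9,
                     enso_sd: float = 0.8) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate daily weather and a monthly ENSO index.

    Daily maximum temperature is a sinusoid on the annual cycle plus noise;
    the minimum sits a strictly positive spread below it.  Rainfall is
    gamma-distributed with a wet-season (May-Dec) multiplier.  The ENSO
    index is a stationary AR(1) on months with autocorrelation ``enso_phi``
    and marginal standard deviation ``enso_sd``.

    Returns ``(daily, enso)``: daily has columns date, tmax, tmin,
    rainfall, solar_rad, soil_humidity; enso has year, month, enso.
    """
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31",
                          freq="D")
    doy = dates.day_of_year.to_numpy()
    cycle = np.cos(2 * np.pi * (doy - 105) / 365.25)
    tmax = 31.0 + 1.5 * cycle + rng.normal(0, noise_sd, len(dates))
    spread = np.maximum(0.5, 7.0 - 1.0 * cycle + rng.normal(0, noise_sd, len(dates)))
    tmin = tmax - spread
    wet = np.asarray(dates.month >= 5)
    rain_scale = np.where(wet, 9.0, 1.5)
    rainfall = rng.gamma(0.6, rain_scale, len(dates))
    solar = np.maximum(0.0, 18.0 + 4.0 * cycle + rng.normal(0, 2 * noise_sd, len(dates)))
    soil = np.clip(0.25 + 0.25 * wet + rng.normal(0, 0.05 * noise_sd, len(dates)),
                   0.01, 1.0)
    daily = pd.DataFrame({"date": dates, "tmax": tmax, "tmin": tmin,
                          "rainfall": rainfall, "solar_rad": solar,
                          "soil_humidity": soil})

    n_months = 12 * n_years
    innov_sd = enso_sd * np.sqrt(max(1e-12, 1 - enso_phi ** 2))
    e = np.empty(n_months)
    e[0] = rng.normal(0, enso_sd)
    shocks = rng.normal(0, innov_sd, n_months)
    for k in range(1, n_months):
        e[k] = enso_phi * e[k - 1] + shocks[k]
    months = pd.period_range(f"{start_year}-01", periods=n_months, freq="M")
    enso = pd.DataFrame({"year": months.year, "month": months.month, "enso": e})
    return daily, enso


def simulate_bundle(spec: SimulationSpec | None = None, seed: int = 0,
                    signal: float | None = 1.0, outdir=None) -> dict:
    """Generate a coherent counts + traits + hosts + tree + climate bundle.

    The annual-mean ENSO from the simulated climate drives the count model,
    so lagged-climate analyses have genuine structure to find.  With
    ``outdir`` set, writes counts.csv, traits.csv, hosts.csv, tree.nwk,
    climate.csv and enso.csv there.
    """
    from .io import write_count_table, write_newick

    spec = spec or SimulationSpec()
    rng = np.random.default_rng(seed)
    sub = [int(x) for x in rng.integers(2 ** 31, size=4)]
    daily, enso = simulate_climate(spec.n_years, seed=sub[0],
                                   start_year=spec.start_year)
    annual_enso = enso.groupby("year")["enso"].mean().to_numpy()
    spec = dataclasses.replace(spec, enso=annual_enso, seed=sub[1])
    records = simulate_counts(spec)
    tree, traits, hosts = simulate_tree_and_traits(
        spec.n_species, signal=signal, seed=sub[2])
    bundle = {"records": records, "tree": tree, "measurements": traits,
              "hosts": hosts, "climate": daily, "enso": enso, "spec": spec}
    if outdir is not None:
        import pathlib
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_count_table(records, outdir / "counts.csv")
        traits.to_csv(outdir / "traits.csv", index=False)
        hosts.to_csv(outdir / "hosts.csv", index=False)
        write_newick(tree, outdir / "tree.nwk")
        daily.to_csv(outdir / "climate.csv", index=False)
        enso.to_csv(outdir / "enso.csv", index=False)
    return bundle
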