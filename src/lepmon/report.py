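"""End-to-end monitoring report: traits -> groups -> trends -> forecasts.

``run_report`` orchestrates the full analysis chain on one input bundle and
returns a structured, JSON-serialisable report: per-species and per-group
trend fits with categories (the monitoring table), functional clusters and
their phylogenetic-clustering tests, forecasts, climate regressions, and
community metrics.  Stages degrade gracefully: a missing input or a stage
failure is recorded in the report without aborting the rest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings

import numpy as np
import pandas as pd

from . import climate as climate_mod
from . import community as community_mod
from .forecast import forecast_seasonal
from .functional import build_functional_space, cluster_functional_groups
from .io import annualize, observed_site_years
from .phylo import mpd_permutation_test, patristic_matrix
from .traits import assemble_trait_matrix, build_trait_table
from .trend import TrimModel, select_model

__all__ = ["select_common_species", "run_report", "MonitoringReport"]


def select_common_species(records: pd.DataFrame,
                          min_total: int = 32) -> list[str]:
    """Species abundant enough for trend modelling.

    Inclusion requires a total catch above *min_total* over the monitoring
    period and a presence (count > 0) in every study year — the practical
    reading of "well sampled in each of the study years".
    """
    years = set(records["year"].unique())
    out = []
    for species, sub in records.groupby("species_id"):
        if sub["count"].sum() <= min_total:
            continue
        seen_years = set(sub.loc[sub["count"] > 0, "year"].unique())
        if seen_years == years:
            out.append(species)
    return sorted(out)


@dataclasses.dataclass
class MonitoringReport:
    trend_table: list            # per species/group dicts (the Table-2 shape)
    clusters: dict | None
    mpd_tests: dict | None
    forecasts: dict
    regressions: dict
    community: dict
    provenance: dict
    errors: dict

    def to_json(self, **kwargs) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, sort_keys=True, default=_jsonify, **kwargs)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"cannot serialise {type(obj)}")


def _config_hash(config: dict) -> str:
    blob = json.dumps({k: str(v) for k, v in sorted(config.items())})
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _annual_matrix_for(records, species_list, observed, label):
    """Site x year matrix summed over a set of member species."""
    sub = records[records["species_id"].isin(species_list)]
    counts = pd.DataFrame(0.0, index=observed.index, columns=observed.columns)
    agg = sub.groupby(["site_id", "year"])["count"].sum()
    for (site, year), value in agg.items():
        counts.loc[site, year] = float(value)
    return counts.where(observed, other=np.nan)


def _fit_trend_row(matrix, label: str) -> dict:
    fits = []
    for model in (1, 2, 3):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits.append(TrimModel(matrix, model=model).fit())
        except Exception:
            continue
    if not fits:
        return {"name": label, "status": "no model could be fitted"}
    best, none_sig = select_model(fits)
    row = {"name": label, "status": "ok", "best_model": best.model.model,
           "gof_p": best.gof_p, "aic": best.aic,
           "none_significant": bool(none_sig)}
    if best.model.model != 1:
        m, se = best.overall_slope()
        row.update({"multiplicative_slope": m, "slope_se": se,
                    "category": best.trend_category})
    return row


def _survey_series(records: pd.DataFrame, species=None) -> pd.Series:
    sub = records if species is None else records[
        records["species_id"].isin(species)]
    series = (sub.groupby(["year", "survey_index"])["count"].sum()
              .sort_index())
    return series


def run_report(records: pd.DataFrame, *, measurements=None, hosts=None,
               tree=None, climate=None, enso=None, seed: int = 0,
               k_clusters: int = 5, n_perm: int = 999,
               forecast_horizon: int = 8, config: dict | None = None
               ) -> MonitoringReport:
    """Run every analysis stage available for the provided inputs.

    Trait/cluster/phylogeny stages run only when measurements, hosts and a
    tree are given; climate regressions and the CCA only when climate and
    ENSO series are given.  Failures are recorded per stage in ``errors``.
    """
    rng_seed = int(seed)
    errors: dict[str, str] = {}
    observed = observed_site_years(records)
    species_sel = select_common_species(records)

    # --- traits, functional groups, phylogenetic structure ---------------
    clusters_out = None
    mpd_out = None
    assignment = None
    if measurements is not None and hosts is not None:
        try:
            trait_table = build_trait_table(measurements, records, hosts)
            matrix = assemble_trait_matrix(trait_table)
            space = build_functional_space(matrix)
            assignment = cluster_functional_groups(space, k=k_clusters,
                                                   traits=trait_table)
            clusters_out = {
                "k": assignment.k,
                "labels": {s: int(l) for s, l in assignment.labels.items()},
                "silhouette": assignment.silhouette,
                "eigenvalues": space.eigenvalues.tolist(),
                "cluster_trait_means": {
                    str(c): {t: float(v) for t, v in row.items()}
                    for c, row in assignment.cluster_means.iterrows()},
            }
        except Exception as exc:                        # pragma: no cover
            errors["functional"] = str(exc)
    else:
        errors["functional"] = "skipped: trait measurements or hosts missing"

    if assignment is not None and tree is not None:
        try:
            dist = patristic_matrix(tree)
            shared = [s for s in assignment.labels.index if s in dist.index]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tests = mpd_permutation_test(
                    dist, assignment.labels.loc[shared], n_perm=n_perm,
                    seed=rng_seed)
            mpd_out = {str(c): r.to_dict() for c, r in tests.items()}
        except Exception as exc:                        # pragma: no cover
            errors["phylo"] = str(exc)
    elif tree is None:
        errors["phylo"] = "skipped: tree missing"

    # --- trends: species, functional clusters ----------------------------
    trend_table = []
    all_species = sorted(records["species_id"].unique())
    trend_table.append(_fit_trend_row(
        _annual_matrix_for(records, all_species, observed, "all"), "all"))
    for sp in species_sel:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trend_table.append(_fit_trend_row(
                annualize(records, sp, observed=observed), sp))
    if assignment is not None:
        for c in sorted(assignment.labels.unique()):
            members = assignment.members(c)
            trend_table.append(_fit_trend_row(
                _annual_matrix_for(records, members, observed, f"cluster{c}"),
                f"cluster{c}"))

    # --- forecasts --------------------------------------------------------
    forecasts = {}
    try:
        series = _survey_series(records)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fc = forecast_seasonal(series.to_numpy(dtype=float),
                                   horizon=forecast_horizon)
        forecasts["all"] = fc.to_dict()
    except Exception as exc:
        errors["forecast"] = str(exc)

    # --- climate regressions + community metrics -------------------------
    regressions = {}
    community = {}
    surveys = (records[["date", "year", "survey_index"]]
               .drop_duplicates(["year", "survey_index"]))
    if climate is not None and enso is not None:
        try:
            cov = climate_mod.build_covariates(climate, enso, surveys)
            y = np.log1p(_survey_series(records).to_numpy(dtype=float))
            res = climate_mod.stepwise_regress(y, cov)
            regressions["all"] = res.to_dict()
        except Exception as exc:
            errors["climate"] = str(exc)
    else:
        errors["climate"] = "skipped: climate or ENSO series missing"

    try:
        pivot = (records.groupby(["year", "survey_index", "species_id"])["count"]
                 .sum().unstack(fill_value=0))
        inc = (pivot.T > 0)
        community["ice"] = community_mod.ice_estimate(inc).to_dict()
        acc = community_mod.accumulation_curve(inc, n_rand=100, seed=rng_seed)
        community["accumulation_final"] = float(acc["mean_richness"].iloc[-1])
        annual = records.groupby(["year", "species_id"])["count"].sum().unstack(
            fill_value=0)
        years = list(annual.index)
        sim = {f"{y1}-{y2}": community_mod.morisita_horn(
            annual.loc[y1], annual.loc[y2])
            for i, y1 in enumerate(years) for y2 in years[i + 1:]}
        community["morisita_horn"] = sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ord_res = community_mod.nmds(annual, seed=rng_seed)
        community["nmds_stress"] = ord_res.stress
        totals = annual.sum(axis=1).to_numpy(dtype=float)
        community["nmds_axis1_abundance_r"] = ord_res.axis_correlation(totals)
        if climate is not None and enso is not None and "climate" not in errors:
            comp = pivot.copy()
            comp.index = [f"{y}_{t}" for y, t in comp.index]
            covx = cov.set_index(
                cov["year"].astype(str) + "_" + cov["survey_index"].astype(str))
            use_cols = ["dd30", "tmin30", "rain_month_sum", "soil_month_mean",
                        "solar_month_mean", "enso"]
            use_cols = [c for c in use_cols if c in covx.columns]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cres = community_mod.cca(comp, covx[use_cols],
                                         n_perm=199, seed=rng_seed)
            community["cca"] = {
                "constrained_fraction": cres.constrained_fraction,
                "pseudo_f": cres.pseudo_f, "p_value": cres.p_value}
    except Exception as exc:
        errors["community"] = str(exc)

    provenance = {
        "seed": rng_seed,
        "config_hash": _config_hash(config or {}),
        "n_records": int(len(records)),
        "n_species_selected": len(species_sel),
        "selected_species": species_sel,
    }
    return MonitoringReport(trend_table=trend_table, clusters=clusters_out,
                            mpd_tests=mpd_out, forecasts=forecasts,
                            regressions=regressions, community=community,
                            provenance=provenance, errors=errors)
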