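"""Derived species traits: wing load, seasonality (Var_Peak), diet breadth.

The functional classification rests on five variables per species: forewing
length (FW, mm), thorax width (TW, mm), their ratio (wing load, an index of
flight strength), a seasonality index (Var_Peak) measuring how repeatable
the survey of peak abundance is across years, and a diet-breadth index
(DBIF) — the fraction of host-plant families in the reference database a
species is recorded from.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRAIT_COLUMNS = ["FW", "TW", "WingLoad", "Var_Peak", "DBIF"]


def compute_wing_load(fw: float, tw: float) -> float:
    """Thorax width / forewing length: heavier-bodied relative to wing span
    means stronger flight."""
    if fw <= 0 or tw <= 0:
        raise ValueError("FW and TW must be positive")
    return tw / fw


def compute_var_peak(records: pd.DataFrame, species: str) -> float:
    """Circular variance of the yearly peak survey on the 4-survey cycle.

    For every year in which the species was caught at all, the peak survey
    is the one with the largest site-summed count (ties to the earliest
    survey).  Peaks are placed on the circle at angles 2*pi*(p-1)/4 and
    Var_Peak = 1 - R, the circular variance of those positions: 0 when the
    peak falls in the same survey every year (strict seasonality), 1 when
    peaks are uniform around the cycle.  NaN if the species is never seen.
    """
    sub = records[records["species_id"] == species]
    if sub.empty:
        raise KeyError(f"unknown species {species!r}")
    by_year = sub.groupby(["year", "survey_index"])["count"].sum().unstack(
        fill_value=0).reindex(columns=[1, 2, 3, 4], fill_value=0)
    totals = by_year.sum(axis=1)
    by_year = by_year[totals > 0]
    if by_year.empty:
        return float("nan")
    peaks = by_year.to_numpy().argmax(axis=1)  # argmax takes first maximum
    theta = 2 * np.pi * peaks / 4
    resultant = np.hypot(np.cos(theta).mean(), np.sin(theta).mean())
    return float(1.0 - resultant)


def compute_dbif(hosts: pd.DataFrame, species: str) -> float:
    """Distinct host families of *species* over distinct families overall."""
    if hosts.empty:
        raise ValueError("host record table is empty")
    total = hosts["plant_family"].nunique()
    used = hosts.loc[hosts["species_id"] == species, "plant_family"].nunique()
    if used == 0:
        return float("nan")
    return used / total


def build_trait_table(measurements: pd.DataFrame, records: pd.DataFrame,
                      hosts: pd.DataFrame) -> pd.DataFrame:
    """Assemble the five-variable trait table for species with complete data.

    *measurements* needs columns species_id, FW, TW.  Species missing a
    Var_Peak (never caught) or a DBIF (no host records) get NaN and are the
    caller's to drop before analysis.
    """
    rows = []
    for r in measurements.itertuples():
        try:
            vp = compute_var_peak(records, r.species_id)
        except KeyError:
            vp = float("nan")
        rows.append({
            "species_id": r.species_id,
            "FW": float(r.FW),
            "TW": float(r.TW),
            "WingLoad": compute_wing_load(r.FW, r.TW),
            "Var_Peak": vp,
            "DBIF": compute_dbif(hosts, r.species_id),
        })
    return pd.DataFrame(rows).set_index("species_id").sort_index()


def assemble_trait_matrix(traits: pd.DataFrame) -> pd.DataFrame:
    """Z-standardise the complete trait rows into the analysis matrix.

    Columns are centred and scaled to unit sample standard deviation so the
    subsequent PCA acts on the correlation structure; traits are on
    incommensurable scales (mm, ratios, indices).  Row order is stable by
    species id.  Raises on zero-variance traits (naming them) and on
    matrices with fewer than two species.
    """
    cols = [c for c in TRAIT_COLUMNS if c in traits.columns]
    mat = traits[cols].dropna().sort_index()
    if len(mat) < 2:
        raise ValueError("need at least 2 complete species rows to standardise")
    sd = mat.std(ddof=1)
    dead = [c for c in mat.columns if mat[c].nunique() == 1 or sd[c] == 0]
    if dead:
        raise ValueError(f"zero-variance trait column(s): {dead}")
    return (mat - mat.mean()) / sd
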