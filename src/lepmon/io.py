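"""Survey-record ingestion, annual count matrices, and Newick tree IO.

Survey records are carried as a pandas DataFrame in "long" format with
columns ``site_id, date, year, survey_index, species_id, count`` — one row
per (site, survey, species) after aggregation.  Light-trap programmes of the
kind modelled here run four surveys per year (one dry-season, three
wet-season), so calendar dates are mapped to a survey index 1–4 by nearest
anchor month.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

RECORD_COLUMNS = ["site_id", "date", "year", "survey_index", "species_id", "count"]

#: anchor months of the four annual surveys (dry: Mar; wet: May, Sep, Nov)
DEFAULT_ANCHOR_MONTHS = (3, 5, 9, 11)


class SurveyCalendar:
    """Maps calendar dates to (year, survey_index) by nearest anchor month.

    Month distance is circular (December is one month from January); ties
    resolve to the earliest anchor.  The year is the calendar year of the
    date, so a late-December survey belongs to survey 4 of its own year.
    """

    def __init__(self, anchor_months: Sequence[int] = DEFAULT_ANCHOR_MONTHS):
        anchors = tuple(int(m) for m in anchor_months)
        if len(anchors) != 4 or not all(1 <= m <= 12 for m in anchors):
            raise ValueError("anchor_months must be four months in 1..12")
        self.anchor_months = anchors

    def survey_index(self, month: int) -> int:
        diffs = [min(abs(month - a), 12 - abs(month - a)) for a in self.anchor_months]
        return int(np.argmin(diffs)) + 1

    def assign(self, dates: pd.Series) -> pd.DataFrame:
        months = dates.dt.month
        idx = months.map(self.survey_index)
        return pd.DataFrame({"year": dates.dt.year.astype(int),
                             "survey_index": idx.astype(int)})


@dataclasses.dataclass
class AnnualSiteMatrix:
    """Annual summed counts f_ij of one species at I sites over J years."""

    species_id: str
    counts: pd.DataFrame          # sites x years, float (0 where observed-empty)
    observed_mask: pd.DataFrame   # sites x years, bool; False = no surveys ran

    @property
    def sites(self) -> list:
        return list(self.counts.index)

    @property
    def years(self) -> list:
        return list(self.counts.columns)

    def __post_init__(self):
        if self.counts.shape != self.observed_mask.shape:
            raise ValueError("counts and observed_mask shapes differ")
        observed = self.counts.to_numpy()[self.observed_mask.to_numpy()]
        if (observed < 0).any():
            raise ValueError("negative counts in annual matrix")


def _validate_counts(counts: pd.Series) -> np.ndarray:
    arr = pd.to_numeric(counts, errors="coerce")
    bad = arr.isna() | (arr < 0) | (arr % 1 != 0)
    if bad.any():
        row = int(bad[bad].index[0])
        raise ValueError(
            f"invalid count {counts.iloc[row]!r} at row {row}: counts must be "
            "non-negative integers"
        )
    return arr.to_numpy(dtype=np.int64)


def records_from_frame(frame: pd.DataFrame,
                       calendar: SurveyCalendar | None = None) -> pd.DataFrame:
    """Normalise a raw site/date/species/count table into survey records.

    Duplicate (site, date, species) rows are aggregated by summation;
    dates are parsed and mapped to (year, survey_index) via *calendar*.
    """
    calendar = calendar or SurveyCalendar()
    required = {"site", "date", "species", "count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    frame = frame.reset_index(drop=True)
    counts = _validate_counts(frame["count"])
    dates = pd.to_datetime(frame["date"], errors="coerce", format="mixed")
    if dates.isna().any():
        row = int(dates[dates.isna()].index[0])
        raise ValueError(f"unparseable date {frame['date'].iloc[row]!r} at row {row}")
    out = pd.DataFrame({
        "site_id": frame["site"].astype(str),
        "date": dates,
        "species_id": frame["species"].astype(str),
        "count": counts,
    })
    out = pd.concat([out, calendar.assign(out["date"])], axis=1)
    # aggregate duplicate keys; keep the earliest date of each survey cell
    grouped = (out.groupby(["site_id", "year", "survey_index", "species_id"],
                           as_index=False)
               .agg(count=("count", "sum"), date=("date", "min")))
    return grouped[RECORD_COLUMNS].sort_values(
        ["site_id", "year", "survey_index", "species_id"]).reset_index(drop=True)


def read_count_table(path, calendar: SurveyCalendar | None = None) -> pd.DataFrame:
    """Read a delimited count table (columns site, date, species, count)."""
    return records_from_frame(pd.read_csv(path), calendar=calendar)


def write_count_table(records: pd.DataFrame, path) -> None:
    out = records.rename(columns={"site_id": "site", "species_id": "species"})
    out[["site", "date", "species", "count"]].to_csv(path, index=False)


def observed_site_years(records: pd.DataFrame) -> pd.DataFrame:
    """Boolean sites x years mask of site-years with at least one survey row."""
    sites = sorted(records["site_id"].unique())
    years = sorted(records["year"].unique())
    mask = pd.DataFrame(False, index=sites, columns=years)
    for (site, year), _ in records.groupby(["site_id", "year"]):
        mask.loc[site, year] = True
    return mask


def annualize(records: pd.DataFrame, species: str,
              observed: pd.DataFrame | None = None) -> AnnualSiteMatrix:
    """Sum one species' counts into a sites x years annual matrix.

    Cells of site-years in which no surveys ran (for any species) are
    flagged unobserved rather than set to zero; imputation of such cells is
    a trend-model concern, never done at ingest.
    """
    if species not in set(records["species_id"]):
        raise KeyError(f"unknown species {species!r}")
    if observed is None:
        observed = observed_site_years(records)
    sub = records[records["species_id"] == species]
    counts = pd.DataFrame(0.0, index=observed.index, columns=observed.columns)
    agg = sub.groupby(["site_id", "year"])["count"].sum()
    for (site, year), value in agg.items():
        counts.loc[site, year] = float(value)
    counts = counts.where(observed, other=np.nan)
    return AnnualSiteMatrix(species_id=species, counts=counts,
                            observed_mask=observed.copy())


def total_count(records: pd.DataFrame) -> int:
    return int(records["count"].sum())


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(path_or_string, allow_missing_lengths: bool = False) -> dendropy.Tree:
    """Read a rooted Newick tree, validating tip labels and branch lengths."""
    src = str(path_or_string)
    kwargs = dict(schema="newick", preserve_underscores=True)
    try:
        if src.strip().startswith("(") and ";" in src:
            tree = dendropy.Tree.get(data=src, **kwargs)
        else:
            tree = dendropy.Tree.get(path=src, **kwargs)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels in tree: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            if allow_missing_lengths:
                edge.length = 0.0
            else:
                raise ValueError("tree has branches without lengths")
        elif edge.length < 0 or not np.isfinite(edge.length):
            raise ValueError(f"invalid branch length {edge.length}")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True, real_value_format_specifier=".12g")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]
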