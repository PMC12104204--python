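"""Build gridded annual encounter histories from sighting and effort tables.

Raw photo-identification sightings (individual, date, latitude) are assigned
to latitude bins, aggregated to annual per-bin counts ``S[i, l, t]``, and
paired with annual per-bin survey effort ``e[l, t]`` (km² surveyed). Only
individuals seen on at least ``min_days`` distinct survey days in at least
one year carry enough information to estimate space-use parameters; those
individuals are retained for *all* study years (the model's presence
indicator absorbs years in which they were unobserved), with per-year
inclusion flags recording which individual-years met the criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import LatitudeGrid

__all__ = ["EncounterArray", "assign_latitude_bins", "count_survey_days",
           "build_encounter_array"]


@dataclass
class EncounterArray:
    """Annual spatially explicit encounter histories plus effort.

    Attributes
    ----------
    S : ndarray of int, shape (n_individuals, n_bins, n_years)
        Sighting counts per individual, latitude bin and year.
    e : ndarray of float, shape (n_bins, n_years)
        Area surveyed (km²) per bin and year.
    survey_days : ndarray of int, shape (n_individuals, n_years)
        Distinct survey days on which each individual was seen each year.
    included : ndarray of bool, shape (n_individuals, n_years)
        Which individual-years met the minimum-days criterion.
    individuals, years : index maps for the first and last axes of ``S``.
    """

    S: np.ndarray
    e: np.ndarray
    survey_days: np.ndarray
    included: np.ndarray
    individuals: list
    years: list
    min_days: int = 5

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_years(self) -> int:
        return len(self.years)


def assign_latitude_bins(sightings: pd.DataFrame, grid: LatitudeGrid) -> pd.DataFrame:
    """Attach a 1-based ``bin_index`` to each sighting; drop out-of-extent rows.

    Bins are half-open with the lower edge inclusive, so a latitude exactly on
    a shared edge falls in the more northerly bin. Dropped rows are reported
    through a warning carrying their count.
    """
    out = sightings.copy()
    out["bin_index"] = grid.bin_of(out["latitude"].to_numpy())
    n_dropped = int((out["bin_index"] == -1).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} sighting(s) outside the grid extent were dropped",
                      stacklevel=2)
    out = out[out["bin_index"] != -1].reset_index(drop=True)
    if out.empty and n_dropped:
        warnings.warn("all sightings fell outside the grid extent", stacklevel=2)
    return out


def count_survey_days(sightings: pd.DataFrame) -> pd.DataFrame:
    """Distinct survey days with at least one sighting, per individual-year.

    Multiple encounters of an individual on one date count as a single survey
    day; the model's inclusion filter is expressed in days, not rows.
    """
    df = sightings.copy()
    dates = pd.to_datetime(df["date"])
    df["date"] = dates.dt.normalize()
    df["year"] = dates.dt.year
    counts = (df.groupby(["individual_id", "year"])["date"].nunique()
              .rename("survey_days").reset_index())
    return counts


def build_encounter_array(sightings: pd.DataFrame, effort: pd.DataFrame,
                          grid: LatitudeGrid, min_days: int = 5) -> EncounterArray:
    """Aggregate binned sightings and daily effort into annual arrays.

    Individuals qualifying (≥ ``min_days`` distinct days) in at least one year
    are retained for every study year. Raises if a sighting falls in a
    (bin, year) with zero recorded effort, since the observation model assigns
    such events probability zero.
    """
    if sightings.empty:
        raise ValueError("no individuals meet inclusion threshold: empty sightings table")
    if "bin_index" not in sightings.columns:
        sightings = assign_latitude_bins(sightings, grid)

    eff = effort.copy()
    eff["year"] = pd.to_datetime(eff["date"]).dt.year
    if (eff["area_km2"] < 0).any():
        raise ValueError("effort must be non-negative")
    years = sorted(eff["year"].unique())
    year_ix = {y: t for t, y in enumerate(years)}
    e = np.zeros((grid.n_bins, len(years)))
    agg = eff.groupby(["bin_index", "year"])["area_km2"].sum()
    for (l, y), v in agg.items():
        e[int(l) - 1, year_ix[y]] = v

    sig = sightings.copy()
    sig["date"] = pd.to_datetime(sig["date"]).dt.normalize()
    sig["year"] = sig["date"].dt.year
    missing_years = set(sig["year"].unique()) - set(years)
    if missing_years:
        raise ValueError(f"sightings in years with no effort table coverage: {sorted(missing_years)}")

    days = count_survey_days(sig)
    qualified = days[days["survey_days"] >= min_days]["individual_id"].unique()
    if len(qualified) == 0:
        raise ValueError("no individuals meet inclusion threshold "
                         f"(min_days={min_days})")
    individuals = sorted(qualified)
    ind_ix = {ind: i for i, ind in enumerate(individuals)}
    sig = sig[sig["individual_id"].isin(ind_ix)]

    # sightings recorded where no effort was logged contradict the data model
    bad = sig[e[sig["bin_index"].to_numpy(int) - 1,
                sig["year"].map(year_ix).to_numpy(int)] == 0]
    if not bad.empty:
        rows = bad[["individual_id", "date", "bin_index"]].head(10).to_dict("records")
        raise ValueError(f"{len(bad)} sighting(s) fall in zero-effort (bin, year) cells: {rows}")

    S = np.zeros((len(individuals), grid.n_bins, len(years)), dtype=int)
    counts = sig.groupby(["individual_id", "bin_index", "year"]).size()
    for (ind, l, y), c in counts.items():
        S[ind_ix[ind], int(l) - 1, year_ix[y]] = c

    survey_days = np.zeros((len(individuals), len(years)), dtype=int)
    for row in days.itertuples(index=False):
        if row.individual_id in ind_ix:
            survey_days[ind_ix[row.individual_id], year_ix[row.year]] = row.survey_days
    included = survey_days >= min_days

    return EncounterArray(S=S, e=e, survey_days=survey_days, included=included,
                          individuals=list(individuals), years=list(years),
                          min_days=min_days)
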