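"""Occurrence-record cleaning: filtering, season split, dedup, spatial thinning.

Records are Darwin-Core-like rows (longitude, latitude, year, month,
basis_of_record).  The cleaning funnel mirrors standard presence-data
practice for niche modeling: keep preserved specimens inside a year window,
split by meteorological season, drop exact coordinate duplicates within each
season, then rarefy so no two retained records fall within a distance window
(10 km by default), which lowers spatial autocorrelation and sampling bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COLUMNS",
    "SEASON_MONTHS",
    "filter_occurrences",
    "assign_season",
    "split_by_season",
    "dedupe_exact",
    "thin_spatial",
    "read_occurrences_csv",
]

#: default CSV column mapping (Darwin Core names -> internal names)
DEFAULT_COLUMNS = {
    "decimalLongitude": "longitude",
    "decimalLatitude": "latitude",
    "year": "year",
    "month": "month",
    "basisOfRecord": "basis_of_record",
}

SEASON_MONTHS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "fall": (9, 10, 11),
    "winter": (12, 1, 2),
}
_MONTH_TO_SEASON = {m: s for s, months in SEASON_MONTHS.items() for m in months}

EARTH_RADIUS_KM = 6371.0088


def read_occurrences_csv(path, columns: dict | None = None) -> pd.DataFrame:
    """Read an occurrence CSV, renaming columns per the mapping."""
    mapping = dict(DEFAULT_COLUMNS if columns is None else columns)
    frame = pd.read_csv(path)
    missing = [c for c in mapping if c not in frame.columns]
    if missing:
        raise ValueError(f"occurrence CSV lacks columns {missing}")
    return frame.rename(columns=mapping)[list(mapping.values())]


def _normalize_basis(value: str) -> str:
    # "PRESERVED_SPECIMEN", "PreservedSpecimen", "preserved specimen" all match
    return str(value).replace("_", "").replace(" ", "").lower()


def filter_occurrences(records: pd.DataFrame, year_min: int = 1970,
                       year_max: int = 2020,
                       basis: str = "PreservedSpecimen") -> pd.DataFrame:
    """Keep records with year in [year_min, year_max] and a matching basis.

    Records missing year or month are dropped (seasonal analysis needs both);
    counts removed by each rule are logged.
    """
    n0 = len(records)
    has_fields = records["year"].notna() & records["month"].notna()
    kept = records[has_fields].copy()
    log.info("dropped %d records missing year or month", n0 - len(kept))
    kept["year"] = kept["year"].astype(int)
    kept["month"] = kept["month"].astype(int)

    in_years = (kept["year"] >= year_min) & (kept["year"] <= year_max)
    log.info("dropped %d records outside %d-%d", int((~in_years).sum()), year_min, year_max)
    kept = kept[in_years]

    target = _normalize_basis(basis)
    basis_ok = kept["basis_of_record"].map(_normalize_basis) == target
    log.info("dropped %d records with basis != %s", int((~basis_ok).sum()), basis)
    return kept[basis_ok].reset_index(drop=True)


def assign_season(month: int) -> str:
    """Meteorological season: Mar-May spring, Jun-Aug summer, Sep-Nov fall, Dec-Feb winter."""
    month = int(month)
    if month not in _MONTH_TO_SEASON:
        raise ValueError(f"month must be in 1..12, got {month}")
    return _MONTH_TO_SEASON[month]


def split_by_season(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition records into the four seasons by month (exhaustive, disjoint)."""
    seasons = records["month"].map(assign_season)
    return {
        s: records[seasons == s].reset_index(drop=True)
        for s in SEASON_MONTHS
    }


def dedupe_exact(records: pd.DataFrame) -> pd.DataFrame:
    """Retain one record per exact (longitude, latitude) pair, first in input order."""
    return records.drop_duplicates(
        subset=["longitude", "latitude"], keep="first"
    ).reset_index(drop=True)


def _pairwise_km(records: pd.DataFrame, metric: str) -> np.ndarray:
    coords = records[["longitude", "latitude"]].to_numpy(float)
    if metric == "euclidean":
        # projected coordinates assumed to be in meters
        return squareform(pdist(coords)) / 1000.0
    if metric == "haversine":
        lon = np.radians(coords[:, 0])[:, None]
        lat = np.radians(coords[:, 1])[:, None]
        dlon = lon - lon.T
        dlat = lat - lat.T
        a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
        return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    raise ValueError(f"unknown metric {metric!r}")


def thin_spatial(records: pd.DataFrame, window_km: float = 10.0, seed: int = 0,
                 metric: str = "euclidean") -> pd.DataFrame:
    """Rarefy records so no two retained points lie within window_km of each other.

    Greedy removal: repeatedly drop the record with the most neighbors closer
    than the window (ties broken by a seeded uniform draw) until no pair
    violates it.  Any algorithm meeting the >= window_km postcondition would
    be conformant; this heuristic keeps many points while staying simple.
    Idempotent on its own output for a fixed seed.
    """
    if len(records) <= 1:
        return records.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    dist = _pairwise_km(records, metric)
    np.fill_diagonal(dist, np.inf)
    adjacency = dist < window_km
    alive = np.ones(len(records), dtype=bool)
    while True:
        counts = (adjacency & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = 0
        worst = counts.max()
        if worst == 0:
            break
        candidates = np.flatnonzero(counts == worst)
        alive[rng.choice(candidates)] = False
    return records[alive].reset_index(drop=True)
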