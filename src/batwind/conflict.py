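"""Turbine/habitat overlap: impact tables, conflict maps, roost-buffer report.

Each turbine is assigned the habitat class of the cell containing it, giving
a season × impact-class table (unlikely / moderate / high potential impact,
plus off-map).  Conflict maps intersect the siting classes with seasonal
habitat classes on high-siting cells only: high siting ∧ high habitat → high
potential conflict; ∧ low-to-moderate → low; ∧ unsuitable → minimum.  The
roost report counts turbines and high-siting area within a 100-km foraging
buffer around each roost; buffer membership is computed from point-to-roost
distances rather than discretized buffer polygons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ORDINAL, PointTable, RasterLayer, extract_at_points, regrid
from .habitat import HIGH, LOW_MODERATE, UNSUITABLE, HabitatClassMap
from .siting import SITING_HIGH, SitingClassMap

log = logging.getLogger(__name__)

__all__ = [
    "IMPACT_CLASSES",
    "CONFLICT_NONE",
    "CONFLICT_MINIMUM",
    "CONFLICT_LOW",
    "CONFLICT_HIGH",
    "ImpactTable",
    "ConflictMap",
    "RoostBufferReport",
    "load_turbines",
    "turbine_impact_table",
    "conflict_map",
    "roost_buffer_overlap",
]

IMPACT_CLASSES = ("unlikely", "moderate", "high", "off_map")
_HABITAT_TO_IMPACT = {UNSUITABLE: "unlikely", LOW_MODERATE: "moderate", HIGH: "high"}

CONFLICT_NONE, CONFLICT_MINIMUM, CONFLICT_LOW, CONFLICT_HIGH = 0, 1, 2, 3
CONFLICT_CLASS_NAMES = {CONFLICT_NONE: "none", CONFLICT_MINIMUM: "minimum",
                        CONFLICT_LOW: "low", CONFLICT_HIGH: "high"}


@dataclass
class ImpactTable:
    counts: pd.DataFrame       # seasons × IMPACT_CLASSES, integer counts
    percentages: pd.DataFrame  # same layout, % of total turbines
    n_turbines: int

    def to_csv(self, path) -> None:
        merged = self.counts.astype(str) + " (" + self.percentages.round(1).astype(str) + "%)"
        merged.to_csv(path, index_label="season")


@dataclass
class ConflictMap:
    classes: RasterLayer
    season: str


@dataclass
class RoostBufferReport:
    per_roost: pd.DataFrame  # roost id, turbines_within, high_siting_area
    pooled_turbines: int
    pooled_high_siting_area: float
    buffer_km: float

    def to_dict(self) -> dict:
        return {
            "buffer_km": self.buffer_km,
            "pooled_turbines": int(self.pooled_turbines),
            "pooled_high_siting_area": float(self.pooled_high_siting_area),
            "per_roost": self.per_roost.to_dict(orient="records"),
        }


def load_turbines(source, min_capacity_kw: float = 65.0,
                  min_rotor_m: float = 30.0,
                  columns: dict | None = None,
                  crs_id: str = "local") -> PointTable:
    """Load and filter a turbine table (CSV path or DataFrame).

    Industrial-scale filters require capacity strictly greater than
    ``min_capacity_kw`` and rotor strictly greater than ``min_rotor_m``;
    a record missing an attribute skips that filter with a warning.
    """
    frame = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if columns:
        frame = frame.rename(columns=columns)
    if not {"x", "y"}.issubset(frame.columns):
        raise ValueError("turbine table needs x and y columns")
    coords = frame[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    if coords.isna().any().any():
        raise ValueError("turbine table has unparseable coordinates")
    frame[["x", "y"]] = coords
    n0 = len(frame)
    for attr, cutoff in (("capacity_kw", min_capacity_kw), ("rotor_m", min_rotor_m)):
        if attr not in frame.columns:
            log.warning("turbine table lacks %s; filter skipped entirely", attr)
            continue
        present = frame[attr].notna()
        if (~present).any():
            log.warning("%d turbines missing %s; filter skipped for them",
                        int((~present).sum()), attr)
        keep = ~present | (frame[attr] > cutoff)
        log.info("dropped %d turbines with %s <= %s", int((~keep).sum()), attr, cutoff)
        frame = frame[keep]
    log.info("kept %d of %d turbines", len(frame), n0)
    frame = frame.reset_index(drop=True)
    if "id" not in frame.columns:
        frame.insert(0, "id", np.arange(len(frame)))
    return PointTable(frame, crs_id=crs_id)


def turbine_impact_table(turbines: PointTable,
                         habitat_maps: dict[str, HabitatClassMap]) -> ImpactTable:
    """Season × impact-class counts and percentages of the total turbine set."""
    n = len(turbines)
    rows = {}
    for season, hmap in habitat_maps.items():
        layer = hmap.classes
        values, inside = extract_at_points(layer, turbines)
        counts = dict.fromkeys(IMPACT_CLASSES, 0)
        on_map = inside & (values != layer.nodata)
        counts["off_map"] = int((~on_map).sum())
        for cls, name in _HABITAT_TO_IMPACT.items():
            counts[name] = int((values[on_map] == cls).sum())
        rows[season] = counts
    counts_df = pd.DataFrame.from_dict(rows, orient="index")[list(IMPACT_CLASSES)]
    pct = counts_df * (100.0 / n) if n else counts_df.astype(float)
    return ImpactTable(counts=counts_df, percentages=pct, n_turbines=n)


def conflict_map(siting_classes: SitingClassMap, habitat_map: HabitatClassMap,
                 regrid_habitat: bool = True) -> ConflictMap:
    """Conflict classes on high-siting cells; everywhere else → none.

    Habitat maps on a different grid are regridded to the siting grid by
    nearest-neighbor when ``regrid_habitat`` is set, otherwise a grid
    mismatch is an error.
    """
    s_layer = siting_classes.classes
    h_layer = habitat_map.classes
    if not h_layer.grid.aligned_with(s_layer.grid):
        if not regrid_habitat:
            raise ValueError("habitat and siting grids differ; enable regrid_habitat")
        h_layer = regrid(h_layer, s_layer.grid, method="nearest")
    s_valid = s_layer.valid_mask()
    h_valid = h_layer.valid_mask()
    high_siting = s_valid & (s_layer.values == SITING_HIGH)
    out = np.full(s_layer.grid.shape, CONFLICT_NONE, dtype=np.int32)
    lookup = {UNSUITABLE: CONFLICT_MINIMUM, LOW_MODERATE: CONFLICT_LOW,
              HIGH: CONFLICT_HIGH}
    for h_cls, c_cls in lookup.items():
        out[high_siting & h_valid & (h_layer.values == h_cls)] = c_cls
    nodata = -1
    out[~s_valid | (high_siting & ~h_valid)] = nodata
    layer = RasterLayer(s_layer.grid, out, nodata=nodata, kind=ORDINAL)
    return ConflictMap(classes=layer, season=habitat_map.season)


def roost_buffer_overlap(roosts: PointTable, turbines: PointTable,
                         siting_classes: SitingClassMap,
                         buffer_km: float = 100.0) -> RoostBufferReport:
    """Turbines and high-siting area within each roost's foraging buffer.

    Membership: Euclidean distance to the roost ≤ buffer (map units assumed
    meters).  The pooled figures use the union of buffers, so nothing is
    double-counted.
    """
    if len(roosts) == 0:
        raise ValueError("need at least one roost")
    buffer_m = buffer_km * 1000.0
    layer = siting_classes.classes
    grid = layer.grid
    tx, ty = turbines.xy
    rx, ry = roosts.xy
    cx, cy = grid.cell_centers()
    high = layer.valid_mask() & (layer.values == SITING_HIGH)
    hx, hy = cx[high], cy[high]

    records = []
    turb_any = np.zeros(len(turbines), dtype=bool)
    cell_any = np.zeros(hx.size, dtype=bool)
    for rid, x0, y0 in zip(roosts.data["id"], rx, ry):
        turb_in = np.hypot(tx - x0, ty - y0) <= buffer_m
        cell_in = np.hypot(hx - x0, hy - y0) <= buffer_m
        turb_any |= turb_in
        cell_any |= cell_in
        records.append({
            "roost_id": rid,
            "turbines_within": int(turb_in.sum()),
            "high_siting_area": float(cell_in.sum() * grid.cell_area),
        })
    return RoostBufferReport(
        per_roost=pd.DataFrame(records),
        pooled_turbines=int(turb_any.sum()),
        pooled_high_siting_area=float(cell_any.sum() * grid.cell_area),
        buffer_km=buffer_km,
    )
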