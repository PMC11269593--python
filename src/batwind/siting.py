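"""Multi-criteria wind-turbine siting suitability.

Six criteria (wind power class, slope, land cover, human population density,
distance to transmission lines, distance to major roads) are each
reclassified to an ordinal 0-4 suitability score and combined as a weighted
sum with weights {wind power class: 3, distance to roads: 2, distance to
transmission lines: 2, land cover: 2, slope: 2, population density: 1},
giving a composite score on 0-48.  Scores 0-16 are "low suitability for
siting", 17-32 "moderate", 33-48 "high".  Military land, protected areas and
1-km airport buffers are excluded (NoData, so excluded ground never shows up
as merely "low suitability").

The reclassification breakpoint tables shipped here are documented,
overridable configuration defaults in the style of published GIS siting
studies; they are not asserted as ground truth from any particular source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .grids import CONTINUOUS, ORDINAL, GridSpec, PointTable, RasterLayer, extract_at_points

__all__ = [
    "SITING_LOW",
    "SITING_MODERATE",
    "SITING_HIGH",
    "DEFAULT_WEIGHTS",
    "CriterionSpec",
    "SitingScoreMap",
    "SitingClassMap",
    "reclassify",
    "distance_to_features",
    "build_exclusion_mask",
    "weighted_overlay",
    "classify_siting",
    "turbine_score_quantile",
    "default_criteria",
]

SITING_LOW, SITING_MODERATE, SITING_HIGH = 0, 1, 2
SITING_CLASS_NAMES = {SITING_LOW: "low", SITING_MODERATE: "moderate",
                      SITING_HIGH: "high"}

DEFAULT_WEIGHTS = {
    "wind_power_class": 3,
    "distance_to_roads": 2,
    "distance_to_transmission": 2,
    "landcover": 2,
    "slope": 2,
    "population_density": 1,
}

MAX_SCORE = 4 * sum(DEFAULT_WEIGHTS.values())  # 48


@dataclass(frozen=True)
class CriterionSpec:
    """One siting criterion: weight plus a reclassification table.

    Either ``mapping`` (category value -> score, closed domain: unmapped
    values are an error) or ``edges``/``scores`` band table with half-open
    [lo, hi) bins; values outside [edges[0], edges[-1]) are an error, so use
    ±inf ends for open coverage.
    """

    name: str
    weight: int
    mapping: dict | None = None
    edges: tuple[float, ...] = ()
    scores: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.weight <= 0 or int(self.weight) != self.weight:
            raise ValueError("weights must be positive integers")
        if self.mapping is None:
            if len(self.edges) != len(self.scores) + 1:
                raise ValueError("band table needs len(edges) == len(scores)+1")
            if list(self.edges) != sorted(self.edges):
                raise ValueError("edges must be ascending")
            bad = [s for s in self.scores if s not in range(5)]
        else:
            bad = [s for s in self.mapping.values() if s not in range(5)]
        if bad:
            raise ValueError(f"scores must lie in 0..4, got {bad}")


@dataclass
class SitingScoreMap:
    score: RasterLayer  # integer raster, values in [0, 48]
    weights: dict


@dataclass
class SitingClassMap:
    classes: RasterLayer
    bounds: tuple[int, int] = (16, 32)


def reclassify(raster: RasterLayer, spec: CriterionSpec) -> RasterLayer:
    """Apply a criterion's reclass table, producing an ordinal 0-4 raster."""
    valid = raster.valid_mask()
    vals = raster.values
    nodata = -1
    out = np.full(raster.grid.shape, nodata, dtype=np.int32)
    if spec.mapping is not None:
        v = vals[valid].astype(int)
        unknown = sorted(set(v.tolist()) - set(spec.mapping))
        if unknown:
            raise ValueError(
                f"criterion {spec.name!r}: values outside reclass table: {unknown}")
        lut = np.vectorize(spec.mapping.__getitem__, otypes=[np.int32])
        out[valid] = lut(v)
    else:
        v = vals[valid].astype(float)
        below = v < spec.edges[0]
        above = v >= spec.edges[-1]
        if below.any() or above.any():
            offenders = np.unique(np.concatenate([v[below], v[above]]))[:10]
            raise ValueError(
                f"criterion {spec.name!r}: values outside band coverage: "
                f"{offenders.tolist()}")
        # np.digitize with right=False puts a value equal to an interior
        # breakpoint into the upper bin (half-open [lo, hi) convention)
        bins = np.digitize(v, spec.edges[1:-1])
        out[valid] = np.asarray(spec.scores, dtype=np.int32)[bins]
    return RasterLayer(raster.grid, out, nodata=nodata, kind=ORDINAL)


def distance_to_features(geometries, grid: GridSpec) -> RasterLayer:
    """Euclidean distance (map units) from each cell center to the nearest geometry."""
    geometries = list(geometries)
    if not geometries:
        raise ValueError("need at least one geometry")
    cx, cy = grid.cell_centers()
    points = shapely.points(cx.ravel(), cy.ravel())
    dist = np.full(points.shape, np.inf)
    for geom in geometries:
        dist = np.minimum(dist, shapely.distance(points, geom))
    return RasterLayer(grid, dist.reshape(grid.shape), kind=CONTINUOUS)


def build_exclusion_mask(grid: GridSpec, military=(), protected=(),
                         airports: PointTable | None = None,
                         airport_buffer_m: float = 1000.0) -> RasterLayer:
    """Boolean raster: True where a cell center is excluded from siting.

    A cell is excluded iff its center falls inside any military or protected
    polygon, or within ``airport_buffer_m`` of an airport point (union
    semantics).
    """
    cx, cy = grid.cell_centers()
    points = shapely.points(cx.ravel(), cy.ravel())
    mask = np.zeros(points.shape, dtype=bool)
    for poly in list(military) + list(protected):
        mask |= shapely.covers(poly, points)
    if airports is not None and len(airports):
        ax, ay = airports.xy
        for x0, y0 in zip(ax, ay):
            mask |= np.hypot(cx.ravel() - x0, cy.ravel() - y0) <= airport_buffer_m
    return RasterLayer(grid, mask.reshape(grid.shape).astype(np.int32),
                       nodata=-1, kind=ORDINAL)


def weighted_overlay(score_rasters: dict[str, RasterLayer],
                     weights: dict[str, int] | None = None,
                     exclusion_mask: RasterLayer | None = None) -> SitingScoreMap:
    """Composite score = Σ weight_i × score_i per cell; excluded/NoData → NoData."""
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    missing = sorted(set(weights) - set(score_rasters))
    if missing:
        raise ValueError(f"missing criterion rasters: {missing}")
    grids = {r.grid for r in score_rasters.values()}
    if len(grids) != 1:
        raise ValueError("criterion rasters must be aligned on one grid")
    grid = next(iter(grids))
    total = np.zeros(grid.shape, dtype=np.int64)
    valid = np.ones(grid.shape, dtype=bool)
    for name, w in weights.items():
        layer = score_rasters[name]
        lv = layer.valid_mask()
        vals = layer.values.astype(np.int64)
        if vals[lv].size and (vals[lv].min() < 0 or vals[lv].max() > 4):
            raise ValueError(f"criterion {name!r} scores must lie in 0..4")
        valid &= lv
        total += np.where(lv, w * vals, 0)
    if exclusion_mask is not None:
        if not exclusion_mask.grid.aligned_with(grid):
            raise ValueError("exclusion mask grid mismatch")
        valid &= exclusion_mask.values == 0
    nodata = -1
    out = np.where(valid, total, nodata).astype(np.int32)
    return SitingScoreMap(
        score=RasterLayer(grid, out, nodata=nodata, kind=ORDINAL),
        weights=weights,
    )


def classify_siting(score_map: SitingScoreMap,
                    bounds: tuple[int, int] = (16, 32)) -> SitingClassMap:
    """Low (0..b1), moderate (b1+1..b2), high (b2+1..48); inclusive integer bounds."""
    layer = score_map.score
    valid = layer.valid_mask()
    vals = layer.values
    max_score = 4 * sum(score_map.weights.values())
    if vals[valid].size and (vals[valid].min() < 0 or vals[valid].max() > max_score):
        raise ValueError(f"scores outside [0, {max_score}]")
    b1, b2 = bounds
    out = np.full(layer.grid.shape, SITING_MODERATE, dtype=np.int32)
    out[vals <= b1] = SITING_LOW
    out[vals > b2] = SITING_HIGH
    nodata = -1
    out = np.where(valid, out, nodata).astype(np.int32)
    return SitingClassMap(
        classes=RasterLayer(layer.grid, out, nodata=nodata, kind=ORDINAL),
        bounds=bounds,
    )


def turbine_score_quantile(turbines: PointTable, score_map: SitingScoreMap,
                           cutoff: int) -> tuple[float, int]:
    """Fraction of turbines on valid cells with score strictly below cutoff.

    Returns (fraction, n_nodata) where n_nodata counts turbines on NoData
    cells or outside the grid (excluded from the denominator).
    """
    values, inside = extract_at_points(score_map.score, turbines)
    on_valid = inside & (values != score_map.score.nodata)
    n_nodata = int((~on_valid).sum())
    if on_valid.sum() == 0:
        return 0.0, n_nodata
    frac = float((values[on_valid] < cutoff).mean())
    return frac, n_nodata


# ---------------------------------------------------------------------------
# Default criterion configuration (documented artifact defaults, overridable)
# ---------------------------------------------------------------------------

def default_criteria(landcover_classes, grid_extent_m: float | None = None,
                     ) -> dict[str, CriterionSpec]:
    """Shipped default reclass tables for the six criteria.

    Land-cover scores spread 4..0 over the observed classes (low class ids
    treated as open/most suitable in the synthetic scenes).  Distance bands
    favor proximity to roads and transmission lines; slope bands favor flat
    ground; population bands favor sparsely settled cells.
    """
    classes = sorted(int(c) for c in landcover_classes)
    k = len(classes)
    lc_map = {c: int(round(4 * (k - 1 - i) / max(k - 1, 1)))
              for i, c in enumerate(classes)}
    inf = float("inf")
    return {
        "wind_power_class": CriterionSpec(
            "wind_power_class", DEFAULT_WEIGHTS["wind_power_class"],
            mapping={1: 0, 2: 1, 3: 2, 4: 3, 5: 4, 6: 4, 7: 4}),
        "distance_to_roads": CriterionSpec(
            "distance_to_roads", DEFAULT_WEIGHTS["distance_to_roads"],
            edges=(0.0, 1000.0, 5000.0, 10000.0, 20000.0, inf),
            scores=(4, 3, 2, 1, 0)),
        "distance_to_transmission": CriterionSpec(
            "distance_to_transmission", DEFAULT_WEIGHTS["distance_to_transmission"],
            edges=(0.0, 1000.0, 5000.0, 10000.0, 20000.0, inf),
            scores=(4, 3, 2, 1, 0)),
        "landcover": CriterionSpec(
            "landcover", DEFAULT_WEIGHTS["landcover"], mapping=lc_map),
        "slope": CriterionSpec(
            "slope", DEFAULT_WEIGHTS["slope"],
            edges=(-inf, 5.0, 10.0, 15.0, 20.0, inf),
            scores=(4, 3, 2, 1, 0)),
        "population_density": CriterionSpec(
            "population_density", DEFAULT_WEIGHTS["population_density"],
            edges=(-inf, 10.0, 50.0, 100.0, 500.0, inf),
            scores=(4, 3, 2, 1, 0)),
    }
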