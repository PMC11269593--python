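"""Seeded synthetic landscapes with the statistical structure the analysis assumes.

The generators emulate the inputs of a seasonal niche-model + turbine-siting
study: spatially autocorrelated continuous climate fields (mean temperature,
solar radiation, water vapor pressure, wind speed, precipitation), a k-class
land-cover field, a known-truth habitat suitability surface built from stated
coefficients, siting criteria (wind power class, slope, population density,
road and transmission-line geometries, exclusion features), turbines placed
preferentially in high-wind cells, and roost points.

Everything is a pure function of (config, seed): the same seed yields
bit-identical rasters, points and geometries.

Continuous fields are white noise smoothed with a uniform disk kernel of a
configurable radius (cheap spatial autocorrelation, not a Gaussian-process
claim), then affinely rescaled to a requested mean and standard deviation.
Seasonal fields mix an independent per-season component with a component
shared across seasons, so seasonal layers differ but correlate, as real
climate layers do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box

from .grids import CATEGORICAL, CONTINUOUS, ORDINAL, GridSpec, PointTable, RasterLayer

__all__ = [
    "LandscapeConfig",
    "TruthModel",
    "SitingCriteria",
    "SEASONS",
    "generate_env_stack",
    "compute_truth_suitability",
    "sample_presences",
    "generate_siting_criteria",
    "generate_turbines",
    "generate_roosts",
]

SEASONS = ("spring", "summer", "fall", "winter")

#: roster of continuous variables with realistic means and spreads
#: (temperature degC, solar radiation kJ m-2 day-1, vapor pressure kPa,
#: wind speed m s-1, precipitation mm per month)
DEFAULT_CONTINUOUS_SPECS: dict[str, tuple[float, float]] = {
    "temperature": (16.0, 7.0),
    "solar_radiation": (15000.0, 4000.0),
    "vapor_pressure": (1.2, 0.45),
    "wind_speed": (4.5, 1.6),
    "precipitation": (55.0, 30.0),
}


@dataclass(frozen=True)
class LandscapeConfig:
    grid: GridSpec
    seed: int = 0
    autocorr_len: float = 6.0
    continuous_specs: dict = field(default_factory=lambda: dict(DEFAULT_CONTINUOUS_SPECS))
    n_landcover_classes: int = 5
    n_seasons: int = 4
    shared_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.autocorr_len < 0:
            raise ValueError("autocorr_len must be >= 0")
        if self.n_landcover_classes < 2:
            raise ValueError("need at least 2 land-cover classes")
        if not 0.0 <= self.shared_weight <= 1.0:
            raise ValueError("shared_weight must lie in [0, 1]")


@dataclass(frozen=True)
class TruthModel:
    """Ground-truth suitability: logistic over features of z-scored variables.

    ``coefficients`` maps feature names to weights; supported names are a bare
    variable (linear), ``var^2`` (quadratic) and ``var_a*var_b`` (product),
    all computed on per-raster z-scores so coefficients are scale-free.
    ``tau`` sets the baseline prevalence (intercept = logit(tau)).
    """

    coefficients: dict
    tau: float = 0.5

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in self.coefficients.values()):
            raise ValueError("truth coefficients must be finite")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")


#: default truth used across the analysis: three nonzero linear terms
DEFAULT_TRUTH = TruthModel(
    coefficients={"temperature": 1.6, "vapor_pressure": 1.1, "precipitation": -0.9}
)


def _disk_kernel(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    if r <= 0:
        return np.ones((1, 1))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    kernel = (xx**2 + yy**2 <= radius**2).astype(float)
    return kernel / kernel.sum()


def smooth_field(rng: np.random.Generator, grid: GridSpec, autocorr_len: float) -> np.ndarray:
    """Standardized (mean 0, sd 1) smoothed white-noise field on the grid."""
    from scipy.signal import fftconvolve

    noise = rng.standard_normal(grid.shape)
    kernel = _disk_kernel(autocorr_len)
    if kernel.size > 1:
        field_ = fftconvolve(noise, kernel, mode="same")
    else:
        field_ = noise
    field_ = field_ - field_.mean()
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _quantile_slice(field_: np.ndarray, k: int) -> np.ndarray:
    """Slice a continuous field into k equal-area integer classes 1..k."""
    edges = np.quantile(field_, np.linspace(0, 1, k + 1)[1:-1])
    return (np.digitize(field_, edges) + 1).astype(np.int32)


def generate_env_stack(config: LandscapeConfig) -> dict[str, dict[str, RasterLayer]]:
    """Per-season environmental stacks: 5 continuous layers + 1 categorical.

    Returns ``{season: {variable: RasterLayer, ..., "landcover": RasterLayer}}``.
    """
    rng = np.random.default_rng(config.seed)
    w = config.shared_weight
    seasons = SEASONS[: config.n_seasons]
    # shared spatial component per variable, mixed with per-season noise
    shared = {
        name: smooth_field(rng, config.grid, config.autocorr_len)
        for name in config.continuous_specs
    }
    shared_lc = smooth_field(rng, config.grid, config.autocorr_len)
    out: dict[str, dict[str, RasterLayer]] = {}
    for season in seasons:
        layers: dict[str, RasterLayer] = {}
        for name, (mean, sd) in config.continuous_specs.items():
            own = smooth_field(rng, config.grid, config.autocorr_len)
            z = w * shared[name] + np.sqrt(max(1.0 - w**2, 0.0)) * own
            z = (z - z.mean()) / z.std()
            layers[name] = RasterLayer(config.grid, mean + sd * z, kind=CONTINUOUS)
        own_lc = smooth_field(rng, config.grid, config.autocorr_len)
        z_lc = w * shared_lc + np.sqrt(max(1.0 - w**2, 0.0)) * own_lc
        layers["landcover"] = RasterLayer(
            config.grid,
            _quantile_slice(z_lc, config.n_landcover_classes),
            nodata=-9999,
            kind=CATEGORICAL,
        )
        out[season] = layers
    return out


def _zscore_valid(layer: RasterLayer) -> np.ndarray:
    valid = layer.valid_mask()
    vals = layer.values.astype(float)
    mu = vals[valid].mean()
    sd = vals[valid].std()
    z = (vals - mu) / (sd if sd > 0 else 1.0)
    z[~valid] = np.nan
    return z


def compute_truth_suitability(env: dict[str, RasterLayer], truth: TruthModel) -> RasterLayer:
    """Cellwise logistic suitability from the truth coefficients; NoData propagates."""
    grids = {layer.grid for layer in env.values()}
    if len(grids) != 1:
        raise ValueError("environmental layers must share one grid")
    grid = next(iter(grids))
    z = {name: _zscore_valid(layer) for name, layer in env.items()
         if layer.kind == CONTINUOUS}
    eta = np.full(grid.shape, np.log(truth.tau / (1.0 - truth.tau)))
    for feat, coef in truth.coefficients.items():
        if "*" in feat:
            a, b = feat.split("*")
            term = z[a] * z[b]
        elif feat.endswith("^2"):
            term = z[feat[:-2]] ** 2
        else:
            term = z[feat]
        eta = eta + coef * term
    suit = 1.0 / (1.0 + np.exp(-eta))
    nodata = -9999.0
    suit = np.where(np.isnan(suit), nodata, suit)
    return RasterLayer(grid, suit, nodata=nodata, kind=CONTINUOUS)


def sample_presences(truth: RasterLayer, n: int, seed: int,
                     replace: bool = True) -> PointTable:
    """Sample presence points at cell centers with probability proportional to truth.

    Sampling is with replacement by default, so exact coordinate duplicates
    occur and downstream occurrence cleaning has genuine work to do.
    """
    rng = np.random.default_rng(seed)
    valid = truth.valid_mask()
    vals = np.where(valid, truth.values.astype(float), 0.0).ravel()
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("truth suitability must lie in [0, 1]")
    total = vals.sum()
    if total <= 0:
        raise ValueError("truth surface has no positive cells")
    if not replace and n > int((vals > 0).sum()):
        raise ValueError("n exceeds available cells for sampling without replacement")
    idx = rng.choice(vals.size, size=n, replace=replace, p=vals / total)
    row, col = np.unravel_index(idx, truth.grid.shape)
    cx, cy = truth.grid.cell_centers()
    return PointTable.from_xy(cx[row, col], cy[row, col], crs_id=truth.grid.crs_id,
                              row=row, col=col)


# ---------------------------------------------------------------------------
# Siting criteria, turbines, roosts
# ---------------------------------------------------------------------------

@dataclass
class SitingCriteria:
    wind_power_class: RasterLayer
    slope: RasterLayer
    population_density: RasterLayer
    landcover: RasterLayer
    roads: list
    transmission_lines: list
    military: list
    protected: list
    airports: PointTable


def _random_polyline(rng: np.random.Generator, grid: GridSpec,
                     n_waypoints: int = 6) -> LineString:
    xs = rng.uniform(grid.x_min, grid.x_max, n_waypoints)
    ys = rng.uniform(grid.y_min, grid.y_max, n_waypoints)
    order = np.argsort(xs)  # sweep left-to-right so lines cross the scene
    return LineString(np.column_stack([xs[order], ys[order]]))


def _random_blob(rng: np.random.Generator, grid: GridSpec,
                 frac_radius: float = 0.06) -> Polygon:
    extent = min(grid.x_max - grid.x_min, grid.y_max - grid.y_min)
    cx = rng.uniform(grid.x_min, grid.x_max)
    cy = rng.uniform(grid.y_min, grid.y_max)
    radius = extent * frac_radius * rng.uniform(0.5, 1.5)
    return Point(cx, cy).buffer(radius, quad_segs=8)


def generate_siting_criteria(config: LandscapeConfig, seed: int,
                             n_roads: int = 5, n_lines: int = 3,
                             n_military: int = 2, n_protected: int = 3,
                             n_airports: int = 3,
                             elevation_relief_m: float = 1500.0) -> SitingCriteria:
    """Synthetic siting inputs on the config grid (seeded, deterministic)."""
    rng = np.random.default_rng(seed)
    grid = config.grid
    wind_field = smooth_field(rng, grid, config.autocorr_len)
    wind_power = RasterLayer(grid, _quantile_slice(wind_field, 7), nodata=-9999,
                             kind=ORDINAL)
    elevation = smooth_field(rng, grid, config.autocorr_len * 2 + 1) * elevation_relief_m
    dzdy, dzdx = np.gradient(elevation, grid.cell_size)
    slope_pct = 100.0 * np.hypot(dzdx, dzdy)
    slope = RasterLayer(grid, slope_pct, kind=CONTINUOUS)
    pop = np.exp(1.5 * smooth_field(rng, grid, config.autocorr_len)) * 20.0
    population = RasterLayer(grid, pop, kind=CONTINUOUS)
    landcover = RasterLayer(
        grid,
        _quantile_slice(smooth_field(rng, grid, config.autocorr_len),
                        config.n_landcover_classes),
        nodata=-9999, kind=CATEGORICAL,
    )
    roads = [_random_polyline(rng, grid) for _ in range(n_roads)]
    lines = [_random_polyline(rng, grid) for _ in range(n_lines)]
    military = [_random_blob(rng, grid) for _ in range(n_military)]
    protected = [_random_blob(rng, grid) for _ in range(n_protected)]
    airports = PointTable.from_xy(
        rng.uniform(grid.x_min, grid.x_max, n_airports),
        rng.uniform(grid.y_min, grid.y_max, n_airports),
        crs_id=grid.crs_id,
    )
    return SitingCriteria(wind_power, slope, population, landcover,
                          roads, lines, military, protected, airports)


def generate_turbines(n: int, wind_power_class: RasterLayer, bias: float,
                      seed: int,
                      capacity_kw_range: tuple[float, float] = (100.0, 4000.0),
                      rotor_m_range: tuple[float, float] = (35.0, 150.0)) -> PointTable:
    """Turbine points at cell centers, sampled with probability ∝ exp(bias × class)."""
    rng = np.random.default_rng(seed)
    grid = wind_power_class.grid
    valid = wind_power_class.valid_mask()
    weights = np.where(valid, np.exp(bias * wind_power_class.values.astype(float)), 0.0)
    weights = weights.ravel()
    if n == 0:
        empty = pd.DataFrame({"id": [], "x": [], "y": [],
                              "capacity_kw": [], "rotor_m": []})
        return PointTable(empty, crs_id=grid.crs_id)
    idx = rng.choice(weights.size, size=n, replace=True, p=weights / weights.sum())
    row, col = np.unravel_index(idx, grid.shape)
    cx, cy = grid.cell_centers()
    return PointTable.from_xy(
        cx[row, col], cy[row, col], crs_id=grid.crs_id,
        row=row, col=col,
        capacity_kw=rng.uniform(*capacity_kw_range, n),
        rotor_m=rng.uniform(*rotor_m_range, n),
    )


def generate_roosts(k: int, grid: GridSpec, seed: int) -> PointTable:
    """k roost points uniform over the grid extent."""
    rng = np.random.default_rng(seed)
    return PointTable.from_xy(
        rng.uniform(grid.x_min, grid.x_max, k),
        rng.uniform(grid.y_min, grid.y_max, k),
        crs_id=grid.crs_id,
    )
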