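"""Grid, raster and point-table data model shared by every pipeline stage.

All analyses run on a single flat projected plane: a :class:`GridSpec` is a
north-up, square-cell grid anchored at its top-left corner, and the CRS is
carried as an opaque identifier string.  Nothing here reprojects coordinates;
all layers and point sets entering one analysis must already share a CRS.

Cell ownership follows a half-open convention: cell (row, col) owns
``[x0, x0 + cs) x (y0 - cs, y0]`` where ``(x0, y0)`` is its top-left corner.
Row/column indices come from flooring offsets from the grid origin, so a point
sitting exactly on a vertical cell boundary belongs to the right-hand cell and
a point on a horizontal boundary to the cell above it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GridSpec",
    "RasterLayer",
    "PointTable",
    "RasterFormatError",
    "read_raster",
    "write_raster",
    "regrid",
    "extract_at_points",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
ORDINAL = "ordinal"
_KINDS = (CONTINUOUS, CATEGORICAL, ORDINAL)

# GeoTIFF tag codes used for round-tripping grid geometry through tifffile.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class RasterFormatError(ValueError):
    """Raised when a file cannot be interpreted as a supported raster."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid with square cells.

    ``x_min`` / ``y_max`` locate the outer top-left corner in map units;
    ``crs_id`` is opaque metadata used only to assert that layers match.
    """

    x_min: float
    y_max: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_id: str = "local"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-center coordinates, shape (n_rows, n_cols)."""
        cs = self.cell_size
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * cs
        ys = self.y_max - (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map coordinates to (row, col, inside) under the half-open convention.

        ``inside`` is False for points outside the grid extent; their row/col
        values are clipped and must not be used.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cs = self.cell_size
        col = np.floor((x - self.x_min) / cs).astype(np.int64)
        # flooring the top-down offset realises the (y0-cs, y0] ownership:
        # y == y_max lands in row 0, an interior horizontal edge in the row below
        row = np.floor((self.y_max - y) / cs).astype(np.int64)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return (
            np.clip(row, 0, self.n_rows - 1),
            np.clip(col, 0, self.n_cols - 1),
            inside,
        )

    def aligned_with(self, other: "GridSpec") -> bool:
        return self == other


@dataclass
class RasterLayer:
    """A single-band gridded variable with an explicit NoData sentinel."""

    grid: GridSpec
    values: np.ndarray
    nodata: float = -9999.0
    kind: str = CONTINUOUS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind in (CATEGORICAL, ORDINAL):
            valid = self.valid_mask()
            vals = self.values[valid]
            if vals.size and not np.allclose(vals, np.round(vals)):
                raise ValueError(f"{self.kind} raster holds non-integer values")

    def valid_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            mask = self.values != self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            mask &= ~np.isnan(self.values)
        return mask

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=~self.valid_mask())

    def with_values(self, values: np.ndarray, kind: str | None = None,
                    nodata: float | None = None) -> "RasterLayer":
        return RasterLayer(
            grid=self.grid,
            values=values,
            nodata=self.nodata if nodata is None else nodata,
            kind=self.kind if kind is None else kind,
        )


@dataclass
class PointTable:
    """Point features with attributes, on the same opaque CRS as the rasters."""

    data: pd.DataFrame
    crs_id: str = "local"

    def __post_init__(self) -> None:
        for col in ("id", "x", "y"):
            if col not in self.data.columns:
                raise ValueError(f"PointTable requires column {col!r}")
        if self.data[["x", "y"]].isna().any().any():
            raise ValueError("PointTable coordinates must not be missing")
        if self.data["id"].duplicated().any():
            raise ValueError("PointTable ids must be unique")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.data["x"].to_numpy(float), self.data["y"].to_numpy(float)

    @classmethod
    def from_xy(cls, x: Iterable[float], y: Iterable[float], crs_id: str = "local",
                **attrs: Iterable) -> "PointTable":
        x = np.asarray(list(x), dtype=float)
        frame = pd.DataFrame({"id": np.arange(len(x)), "x": x, "y": np.asarray(list(y), float)})
        for name, col in attrs.items():
            frame[name] = list(col)
        return cls(frame, crs_id=crs_id)


# ---------------------------------------------------------------------------
# I/O: GeoTIFF (via tifffile tags) and ESRI ASCII grid (plain text)
# ---------------------------------------------------------------------------

def write_raster(raster: RasterLayer, path: str | Path) -> None:
    """Write a raster as GeoTIFF (.tif/.tiff) or ESRI ASCII grid (.asc).

    Round-trips values, grid geometry, NoData and the layer kind exactly
    (bit-exact for integer data).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        _write_geotiff(raster, path)
    elif suffix == ".asc":
        _write_ascii_grid(raster, path)
    else:
        raise RasterFormatError(f"unsupported raster extension {suffix!r} for {path}")


def read_raster(path: str | Path) -> RasterLayer:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return _read_geotiff(path)
    if suffix == ".asc":
        return _read_ascii_grid(path)
    raise RasterFormatError(f"unsupported raster extension {suffix!r} for {path}")


def _write_geotiff(raster: RasterLayer, path: Path) -> None:
    import tifffile

    g = raster.grid
    meta = {"kind": raster.kind, "crs_id": g.crs_id}
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x_min, g.y_max, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{float(raster.nodata):.17g}"),
    ]
    tifffile.imwrite(
        path,
        raster.values,
        description=json.dumps(meta),
        extratags=extratags,
    )


def _read_geotiff(path: Path) -> RasterLayer:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = page.tags
            scale = tags.valueof(_TAG_MODEL_PIXEL_SCALE)
            tiepoint = tags.valueof(_TAG_MODEL_TIEPOINT)
            nodata_str = tags.valueof(_TAG_GDAL_NODATA)
            desc = tags.valueof("ImageDescription")
    except (tifffile.TiffFileError, ValueError) as exc:
        raise RasterFormatError(f"{path} is not a readable TIFF: {exc}") from exc
    if scale is None or tiepoint is None:
        raise RasterFormatError(f"{path} lacks GeoTIFF georeferencing tags")
    meta = {}
    if desc is not None:
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            meta = {}
    if "crs_id" not in meta:
        raise RasterFormatError(f"{path} has no CRS metadata")
    cs = float(scale[0])
    x_min = float(tiepoint[3])
    y_max = float(tiepoint[4])
    nodata = float(nodata_str) if nodata_str is not None else -9999.0
    grid = GridSpec(
        x_min=x_min, y_max=y_max, cell_size=cs,
        n_rows=values.shape[0], n_cols=values.shape[1],
        crs_id=str(meta["crs_id"]),
    )
    return RasterLayer(grid=grid, values=values, nodata=nodata,
                       kind=meta.get("kind", CONTINUOUS))


def _write_ascii_grid(raster: RasterLayer, path: Path) -> None:
    g = raster.grid
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.x_min:.17g}\n"
        f"yllcorner {g.y_min:.17g}\n"
        f"cellsize {g.cell_size:.17g}\n"
        f"NODATA_value {raster.nodata:.17g}\n"
    )
    # %.17g round-trips float64 exactly; integer rasters stay integer-formatted
    fmt = "%d" if np.issubdtype(raster.values.dtype, np.integer) else "%.17g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt=fmt)
    sidecar = {"kind": raster.kind, "crs_id": g.crs_id,
               "dtype": str(raster.values.dtype)}
    Path(str(path) + ".aux.json").write_text(json.dumps(sidecar))


def _read_ascii_grid(path: Path) -> RasterLayer:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline().split()
            if len(line) != 2:
                raise RasterFormatError(f"{path}: malformed ASCII grid header")
            header[line[0].lower()] = float(line[1])
        try:
            values = np.loadtxt(fh, ndmin=2)
        except ValueError as exc:
            raise RasterFormatError(f"{path}: unparseable grid body: {exc}") from exc
    sidecar_path = Path(str(path) + ".aux.json")
    if not sidecar_path.exists():
        raise RasterFormatError(f"{path}: missing .aux.json sidecar with CRS metadata")
    meta = json.loads(sidecar_path.read_text())
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise RasterFormatError(f"{path}: body shape {values.shape} != header")
    cs = header["cellsize"]
    grid = GridSpec(
        x_min=header["xllcorner"],
        y_max=header["yllcorner"] + n_rows * cs,
        cell_size=cs, n_rows=n_rows, n_cols=n_cols,
        crs_id=str(meta["crs_id"]),
    )
    return RasterLayer(grid=grid, values=values.astype(meta.get("dtype", "float64")),
                       nodata=header["nodata_value"], kind=meta.get("kind", CONTINUOUS))


# ---------------------------------------------------------------------------
# Regridding and point extraction
# ---------------------------------------------------------------------------

def regrid(raster: RasterLayer, target: GridSpec,
           method: str = "nearest") -> RasterLayer:
    """Resample a raster onto ``target``.

    ``nearest`` works for every kind; ``bilinear`` only for continuous data;
    ``mode_block`` aggregates categorical/ordinal data by majority vote over
    the source cells whose centers fall in each target cell.
    """
    if raster.grid.crs_id != target.crs_id:
        raise ValueError("regrid requires matching crs_id on source and target")
    if raster.grid.aligned_with(target):
        return RasterLayer(target, raster.values.copy(), raster.nodata, raster.kind)
    if method == "bilinear":
        if raster.kind != CONTINUOUS:
            raise ValueError("bilinear regridding is only valid for continuous rasters")
        return _regrid_bilinear(raster, target)
    if method == "nearest":
        return _regrid_nearest(raster, target)
    if method == "mode_block":
        if raster.kind == CONTINUOUS:
            raise ValueError("mode_block regridding is for categorical/ordinal rasters")
        return _regrid_mode_block(raster, target)
    raise ValueError(f"unknown regrid method {method!r}")


def _regrid_nearest(raster: RasterLayer, target: GridSpec) -> RasterLayer:
    tx, ty = target.cell_centers()
    row, col, inside = raster.grid.index_of(tx.ravel(), ty.ravel())
    out = np.full(tx.size, raster.nodata, dtype=raster.values.dtype)
    out[inside] = raster.values[row[inside], col[inside]]
    return RasterLayer(target, out.reshape(target.shape), raster.nodata, raster.kind)


def _regrid_bilinear(raster: RasterLayer, target: GridSpec) -> RasterLayer:
    src = raster.values.astype(float)
    src = np.where(raster.valid_mask(), src, np.nan)
    g = raster.grid
    tx, ty = target.cell_centers()
    # fractional source-array coordinates of target cell centers
    cols = (tx - g.x_min) / g.cell_size - 0.5
    rows = (g.y_max - ty) / g.cell_size - 0.5
    out = ndimage.map_coordinates(src, [rows.ravel(), cols.ravel()], order=1,
                                  mode="nearest", cval=np.nan)
    out = out.reshape(target.shape)
    # outside the source extent entirely -> nodata
    _, _, inside = g.index_of(tx.ravel(), ty.ravel())
    out[~inside.reshape(target.shape)] = np.nan
    out = np.where(np.isnan(out), raster.nodata, out)
    return RasterLayer(target, out, raster.nodata, CONTINUOUS)


def _regrid_mode_block(raster: RasterLayer, target: GridSpec) -> RasterLayer:
    sx, sy = raster.grid.cell_centers()
    row, col, inside = target.index_of(sx.ravel(), sy.ravel())
    valid = raster.valid_mask().ravel() & inside
    tgt_idx = (row * target.n_cols + col)[valid]
    classes = raster.values.ravel()[valid].astype(np.int64)
    uniq = np.unique(classes)
    n_cells = target.n_rows * target.n_cols
    # votes[cell, class]; ties broken toward the smallest class value
    best_count = np.zeros(n_cells, dtype=np.int64)
    best_class = np.full(n_cells, raster.nodata, dtype=float)
    for c in uniq:
        counts = np.bincount(tgt_idx[classes == c], minlength=n_cells)
        better = counts > best_count
        best_count = np.where(better, counts, best_count)
        best_class = np.where(better, float(c), best_class)
    out = best_class.reshape(target.shape)
    if np.issubdtype(raster.values.dtype, np.integer):
        out = out.astype(raster.values.dtype)
    return RasterLayer(target, out, raster.nodata, raster.kind)


def extract_at_points(raster: RasterLayer, points: PointTable) -> tuple[np.ndarray, np.ndarray]:
    """Look up the raster value under each point.

    Returns ``(values, inside)``: points outside the grid extent get the
    NoData sentinel and ``inside=False``; NoData cells inside the grid get
    the sentinel with ``inside=True``.
    """
    if points.crs_id != raster.grid.crs_id:
        raise ValueError("points and raster must share a CRS")
    x, y = points.xy
    row, col, inside = raster.grid.index_of(x, y)
    values = np.full(len(points), float(raster.nodata))
    values[inside] = raster.values[row[inside], col[inside]].astype(float)
    return values, inside
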