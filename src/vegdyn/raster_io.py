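"""Raster and vector input/output plus grid alignment and masking.

Rasters are multi-band TIFF files with a JSON sidecar (``<file>.json``)
that records the grid (origin, pixel size, CRS id, nodata sentinel) and
the band index — ``[[year, month], ...]`` for monthly stacks, ``[year,
...]`` for annual ones. Line geometries travel as GeoJSON. All inputs to
one analysis must share a CRS; reprojection is out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from scipy import ndimage
from shapely.geometry import LineString, mapping, shape

from .containers import (
    AnnualStack,
    LANDCOVER_LEGEND,
    MaskSet,
    MonthlyStack,
    RasterGrid,
)

__all__ = [
    "write_stack",
    "read_stack",
    "write_raster",
    "read_raster",
    "align_to_grid",
    "rasterize_buffer",
    "build_mask_set",
    "write_lines_geojson",
    "read_lines_geojson",
]


# ---------------------------------------------------------------------------
# TIFF + sidecar round trip
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster(path, values: np.ndarray, grid: RasterGrid, index=None, dtype=None) -> None:
    """Write a (bands, rows, cols) or (rows, cols) array with its sidecar."""
    path = Path(path)
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[None]
    if not grid.conforms(values):
        raise ValueError("array does not conform to grid")
    out = values
    if np.issubdtype(values.dtype, np.floating):
        out = values.copy()
        out[np.isnan(out)] = grid.nodata
        out = out.astype(np.float32 if dtype is None else dtype)
    elif dtype is not None:
        out = values.astype(dtype)
    tifffile.imwrite(path, out, photometric="minisblack")
    meta = {"grid": grid.to_dict()}
    if index is not None:
        meta["index"] = [
            [int(v) for v in np.atleast_1d(i)] for i in index
        ]
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_raster(path, expected_grid: RasterGrid | None = None):
    """Read a TIFF + sidecar; returns (values, grid, index or None).

    Float bands come back with the nodata sentinel mapped to NaN (the
    MODIS-style convention of e.g. -3000 therefore never survives the
    read). Integer bands are returned untouched.
    """
    path = Path(path)
    values = tifffile.imread(path)
    if values.ndim == 2:
        values = values[None]
    meta = json.loads(_sidecar_path(path).read_text())
    grid = RasterGrid.from_dict(meta["grid"])
    if values.shape[-2:] != grid.shape:
        raise ValueError(f"{path}: band shape {values.shape[-2:]} != grid {grid.shape}")
    if expected_grid is not None and grid != expected_grid:
        raise ValueError(f"{path}: grid mismatch with expected grid")
    if np.issubdtype(values.dtype, np.floating):
        values = values.astype(float)
        values[values == grid.nodata] = np.nan
    index = meta.get("index")
    if index is not None:
        index = [tuple(int(v) for v in row) for row in index]
    return values, grid, index


def write_stack(stack: MonthlyStack | AnnualStack, path) -> None:
    if isinstance(stack, MonthlyStack):
        index = [list(ym) for ym in stack.index]
    else:
        index = [[y] for y in stack.years]
    write_raster(path, stack.values, stack.grid, index=index)


def read_stack(paths, expected_grid: RasterGrid | None = None):
    """Read one or more TIFF files into a MonthlyStack or AnnualStack.

    Multiple files must share the grid exactly; their bands are pooled
    and sorted by date. A 1-tuple index means annual, a 2-tuple monthly.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise ValueError("empty stack: no paths given")
    all_values, all_index, grid = [], [], expected_grid
    for p in paths:
        values, g, index = read_raster(p, expected_grid=grid)
        if grid is None:
            grid = g
        if index is None or len(index) != len(values):
            raise ValueError(f"{p}: sidecar lacks a parseable band date index")
        all_values.append(values)
        all_index.extend(index)
    values = np.concatenate(all_values, axis=0)
    order = sorted(range(len(all_index)), key=lambda k: all_index[k])
    values = values[order]
    index = [all_index[k] for k in order]
    if all(len(i) == 2 for i in index):
        return MonthlyStack(grid, [tuple(i) for i in index], values)
    if all(len(i) == 1 for i in index):
        return AnnualStack(grid, [i[0] for i in index], values)
    raise ValueError("mixed monthly/annual band index")


# ---------------------------------------------------------------------------
# Grid alignment (resampling within one CRS)
# ---------------------------------------------------------------------------

def _extent(grid: RasterGrid) -> tuple[float, float, float, float]:
    return (
        grid.origin_x,
        grid.origin_y - grid.n_rows * grid.pixel_size,
        grid.origin_x + grid.n_cols * grid.pixel_size,
        grid.origin_y,
    )


def align_to_grid(
    values: np.ndarray,
    source: RasterGrid,
    target: RasterGrid,
    method: str = "bilinear",
) -> np.ndarray:
    """Resample ``values`` from ``source`` onto ``target`` pixel centers.

    ``bilinear`` is for continuous variables and propagates nodata: any
    NaN among the contributing source pixels makes the target pixel NaN.
    ``nearest`` is for categorical rasters. Target centers outside the
    source extent become nodata.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resampling method {method!r}")
    if source.crs_id != target.crs_id:
        raise ValueError("source and target CRS differ; reprojection unsupported")
    sx0, sy0, sx1, sy1 = _extent(source)
    tx0, ty0, tx1, ty1 = _extent(target)
    if tx0 >= sx1 or tx1 <= sx0 or ty0 >= sy1 or ty1 <= sy0:
        raise ValueError("source and target extents are disjoint")

    values = np.asarray(values)
    squeeze = values.ndim == 2
    bands = values[None] if squeeze else values
    # fractional source pixel indices of target centers
    tx, ty = target.pixel_centers()
    col_f = (tx - source.origin_x) / source.pixel_size - 0.5
    row_f = (source.origin_y - ty) / source.pixel_size - 0.5

    out = np.empty((bands.shape[0],) + target.shape, dtype=float)
    if method == "nearest":
        rows = np.rint(row_f).astype(int)
        cols = np.rint(col_f).astype(int)
        inside = (rows >= 0) & (rows < source.n_rows) & (cols >= 0) & (cols < source.n_cols)
        rows_c = np.clip(rows, 0, source.n_rows - 1)
        cols_c = np.clip(cols, 0, source.n_cols - 1)
        for b in range(bands.shape[0]):
            band = bands[b].astype(float)
            res = band[rows_c, cols_c]
            res[~inside] = np.nan
            out[b] = res
    else:
        inside = (
            (row_f >= 0) & (row_f <= source.n_rows - 1)
            & (col_f >= 0) & (col_f <= source.n_cols - 1)
        )
        coords = np.stack([row_f, col_f])
        for b in range(bands.shape[0]):
            band = bands[b].astype(float)
            # order-1 spline == bilinear; NaN sources poison their 2x2 support
            res = ndimage.map_coordinates(band, coords, order=1, mode="nearest")
            res[~inside] = np.nan
            out[b] = res
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# Line buffers and the mask set
# ---------------------------------------------------------------------------

def rasterize_buffer(
    lines: Iterable[LineString],
    distance: float,
    grid: RasterGrid,
) -> np.ndarray:
    """Boolean raster: True where the pixel center is within ``distance``
    (map units) of any line."""
    if distance < 0:
        raise ValueError("buffer distance must be >= 0")
    lines = list(lines)
    mask = np.zeros(grid.shape, dtype=bool)
    if not lines:
        return mask
    import shapely

    x, y = grid.pixel_centers()
    pts = shapely.points(x.ravel(), y.ravel())
    merged = shapely.union_all(lines)
    d = shapely.distance(pts, merged)
    return (d <= distance).reshape(grid.shape)


def build_mask_set(
    landcover: np.ndarray,
    excluded_classes: Sequence[str | int],
    lines: Iterable[LineString],
    distance: float,
    grid: RasterGrid,
    legend: dict[int, str] = LANDCOVER_LEGEND,
) -> MaskSet:
    """Combine the land-cover exclusion mask with the line-buffer mask.

    ``excluded_classes`` may be class names (looked up in ``legend``) or
    integer codes; unknown entries are an error.
    """
    landcover = np.asarray(landcover)
    name_to_code = {v: k for k, v in legend.items()}
    codes = []
    for c in excluded_classes:
        if isinstance(c, str):
            if c not in name_to_code:
                raise ValueError(f"unknown land-cover class {c!r}")
            codes.append(name_to_code[c])
        else:
            if c not in legend:
                raise ValueError(f"unknown land-cover code {c!r}")
            codes.append(int(c))
    lc_mask = np.isin(landcover, codes)
    buf_mask = rasterize_buffer(lines, distance, grid)
    return MaskSet(landcover_mask=lc_mask, buffer_mask=buf_mask)


# ---------------------------------------------------------------------------
# GeoJSON lines
# ---------------------------------------------------------------------------

def write_lines_geojson(lines: Sequence[LineString], path, properties=None) -> None:
    feats = []
    for i, line in enumerate(lines):
        props = dict(properties[i]) if properties else {}
        feats.append({"type": "Feature", "geometry": mapping(line), "properties": props})
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_lines_geojson(path) -> list[LineString]:
    data = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in data["features"]]
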