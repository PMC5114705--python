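"""Gridded environmental data: grid geometry, raster I/O, cropping, extraction.

All grids are unprojected lon/lat, cell-edge registered, with row 0 the
northernmost row.  Two single-band raster dialects are supported: ESRI
ASCII grid (the portable text format used for fixtures) and GeoTIFF
(read/written through :mod:`tifffile` with the standard geo-tags).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GridSpec",
    "Layer",
    "RasterStack",
    "AlignmentError",
    "cell_area_km2",
    "read_raster",
    "write_raster",
    "read_stack",
    "write_stack",
    "extract_values",
]


class AlignmentError(ValueError):
    """Raised when layers that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a lon/lat raster grid.

    Cell-edge registered: ``lon_min`` / ``lat_max`` are the outer edges of
    the first column / row.  Cells are addressed ``(row, col)`` with row 0
    the northernmost row; a cell center sits at edge + ``cell_size / 2``.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError("latitude bounds must satisfy -90 <= lat_min < lat_max <= 90")
        if abs((self.lon_max - self.lon_min) - self.n_cols * self.cell_size) > 1e-9:
            raise ValueError("lon extent inconsistent with n_cols * cell_size")
        if abs((self.lat_max - self.lat_min) - self.n_rows * self.cell_size) > 1e-9:
            raise ValueError("lat extent inconsistent with n_rows * cell_size")

    # -- coordinate helpers -------------------------------------------------

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes ordered north to south (row order)."""
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def row_lat_edges(self, row: int) -> tuple[float, float]:
        """(north, south) edge latitudes of ``row``."""
        if not 0 <= row < self.n_rows:
            raise IndexError(f"row {row} outside [0, {self.n_rows})")
        north = self.lat_max - row * self.cell_size
        return north, north - self.cell_size

    def rowcol(self, lon: float, lat: float) -> tuple[int, int]:
        """Containing cell of a point, or (-1, -1) if outside the extent.

        A point exactly on an interior cell edge belongs to the cell to its
        north-west (row-0-north indexing makes this the ``ceil - 1`` rule).
        """
        if not (self.lon_min <= lon <= self.lon_max and self.lat_min <= lat <= self.lat_max):
            return -1, -1
        t = (lon - self.lon_min) / self.cell_size
        col = max(math.ceil(t) - 1, 0)
        u = (self.lat_max - lat) / self.cell_size
        row = max(math.ceil(u) - 1, 0)
        return min(row, self.n_rows - 1), min(col, self.n_cols - 1)

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.lon_min - other.lon_min) <= tol
            and abs(self.lat_max - other.lat_max) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


def cell_area_km2(grid: GridSpec, row: int) -> float:
    """True spherical area (km²) of one cell in ``row``.

    Spherical-zone formula ``A = R² Δλ (sin φ_N − sin φ_S)`` with
    R = 6371 km; constant along a row, decreasing toward the poles.
    """
    north, south = grid.row_lat_edges(row)
    dlam = math.radians(grid.cell_size)
    return (
        EARTH_RADIUS_KM**2
        * dlam
        * (math.sin(math.radians(north)) - math.sin(math.radians(south)))
    )


def row_areas_km2(grid: GridSpec) -> np.ndarray:
    """Per-row cell area, shape ``(n_rows,)``."""
    edges = grid.lat_max - np.arange(grid.n_rows + 1) * grid.cell_size
    s = np.sin(np.radians(edges))
    dlam = math.radians(grid.cell_size)
    return EARTH_RADIUS_KM**2 * dlam * (s[:-1] - s[1:])


def cell_area_grid(grid: GridSpec) -> np.ndarray:
    """Cell areas broadcast to the full ``(n_rows, n_cols)`` grid."""
    return np.repeat(row_areas_km2(grid)[:, None], grid.n_cols, axis=1)


@dataclass
class Layer:
    """One named environmental variable on a grid (e.g. BIO1 … BIO19, ELEV)."""

    name: str
    values: np.ndarray
    mask: np.ndarray  # True where nodata

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 2:
            raise ValueError("values and mask must be matching 2-D arrays")


@dataclass
class RasterStack:
    """Aligned named layers sharing one :class:`GridSpec` and a union nodata mask."""

    grid: GridSpec
    layers: list[Layer] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for l in self.layers:
            if l.values.shape != (self.grid.n_rows, self.grid.n_cols):
                raise AlignmentError(f"layer {l.name!r} does not match the grid shape")

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    @property
    def mask(self) -> np.ndarray:
        """Union nodata mask: a cell masked in any layer is masked everywhere."""
        m = np.zeros((self.grid.n_rows, self.grid.n_cols), dtype=bool)
        for l in self.layers:
            m |= l.mask
        return m

    def layer(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "RasterStack":
        return RasterStack(self.grid, [self.layer(n) for n in names])

    def env_matrix(self, names: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(cells × variables) matrix over unmasked cells and their flat indices."""
        names = list(names) if names is not None else self.names
        keep = ~self.mask
        idx = np.flatnonzero(keep)
        cols = [self.layer(n).values[keep] for n in names]
        return np.column_stack(cols), idx

    def crop(self, bbox: tuple[float, float, float, float]) -> "RasterStack":
        """Crop to the smallest cell-aligned window containing ``bbox``.

        ``bbox`` is (lon_min, lat_min, lon_max, lat_max) and must lie within
        the stack extent.
        """
        g = self.grid
        lon0, lat0, lon1, lat1 = bbox
        if not (g.lon_min - 1e-9 <= lon0 <= lon1 <= g.lon_max + 1e-9):
            raise ValueError("bbox longitudes outside stack extent")
        if not (g.lat_min - 1e-9 <= lat0 <= lat1 <= g.lat_max + 1e-9):
            raise ValueError("bbox latitudes outside stack extent")
        c0 = int(math.floor((lon0 - g.lon_min) / g.cell_size + 1e-9))
        c1 = int(math.ceil((lon1 - g.lon_min) / g.cell_size - 1e-9))
        r0 = int(math.floor((g.lat_max - lat1) / g.cell_size + 1e-9))
        r1 = int(math.ceil((g.lat_max - lat0) / g.cell_size - 1e-9))
        c1 = max(c1, c0 + 1)
        r1 = max(r1, r0 + 1)
        c0, c1 = max(c0, 0), min(c1, g.n_cols)
        r0, r1 = max(r0, 0), min(r1, g.n_rows)
        sub = GridSpec(
            lon_min=g.lon_min + c0 * g.cell_size,
            lon_max=g.lon_min + c1 * g.cell_size,
            lat_min=g.lat_max - r1 * g.cell_size,
            lat_max=g.lat_max - r0 * g.cell_size,
            cell_size=g.cell_size,
            n_rows=r1 - r0,
            n_cols=c1 - c0,
        )
        layers = [
            Layer(l.name, l.values[r0:r1, c0:c1].copy(), l.mask[r0:r1, c0:c1].copy())
            for l in self.layers
        ]
        return RasterStack(sub, layers)


# -- raster I/O --------------------------------------------------------------

_ASC_NODATA = -9999.0


def _write_esri_ascii(path: Path, grid: GridSpec, values: np.ndarray, mask: np.ndarray) -> None:
    out = values.copy()
    out[mask] = _ASC_NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.lon_min!r}\n")
        fh.write(f"yllcorner {grid.lat_min!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {_ASC_NODATA:g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def _read_esri_ascii(path: Path) -> tuple[GridSpec, np.ndarray, np.ndarray]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise IOError(f"{path}: missing ESRI ASCII header field {key!r}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    cs = header["cellsize"]
    nodata = header.get("nodata_value", _ASC_NODATA)
    values = np.loadtxt(lines[n_header:], dtype=float).reshape(n_rows, n_cols)
    mask = values == nodata
    grid = GridSpec(
        lon_min=header["xllcorner"],
        lon_max=header["xllcorner"] + n_cols * cs,
        lat_min=header["yllcorner"],
        lat_max=header["yllcorner"] + n_rows * cs,
        cell_size=cs,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return grid, values, mask


# GeoTIFF tag ids: ModelPixelScale, ModelTiepoint, GDAL nodata.
_TAG_SCALE, _TAG_TIEPOINT, _TAG_NODATA = 33550, 33922, 42113


def _write_geotiff(path: Path, grid: GridSpec, values: np.ndarray, mask: np.ndarray) -> None:
    import tifffile

    out = values.astype(np.float64).copy()
    out[mask] = _ASC_NODATA
    extratags = [
        (_TAG_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.lon_min, grid.lat_max, 0.0)),
        (_TAG_NODATA, "s", 0, f"{_ASC_NODATA:g}"),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


def _read_geotiff(path: Path) -> tuple[GridSpec, np.ndarray, np.ndarray]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise IOError(f"{path}: expected a single-band raster")
        tags = page.tags
        if _TAG_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise IOError(f"{path}: missing geo-referencing tags")
        sx, sy = tags[_TAG_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        lon_min, lat_max = tie[3], tie[4]
        nodata = _ASC_NODATA
        if _TAG_NODATA in tags:
            nodata = float(tags[_TAG_NODATA].value)
    if abs(sx - sy) > 1e-9:
        raise IOError(f"{path}: anisotropic cells are not supported")
    n_rows, n_cols = values.shape
    grid = GridSpec(
        lon_min=lon_min,
        lon_max=lon_min + n_cols * sx,
        lat_min=lat_max - n_rows * sx,
        lat_max=lat_max,
        cell_size=sx,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    mask = values == nodata
    return grid, values, mask


def read_raster(path: str | Path) -> tuple[GridSpec, np.ndarray, np.ndarray]:
    """Read a single-band raster; returns (grid, values, nodata mask)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_geotiff(path)
    return _read_esri_ascii(path)


def write_raster(
    path: str | Path, grid: GridSpec, values: np.ndarray, mask: np.ndarray | None = None
) -> None:
    path = Path(path)
    if mask is None:
        mask = ~np.isfinite(values)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_geotiff(path, grid, np.asarray(values, float), np.asarray(mask, bool))
    else:
        _write_esri_ascii(path, grid, np.asarray(values, float), np.asarray(mask, bool))


def read_stack(
    paths: Iterable[str | Path],
    bbox: tuple[float, float, float, float] | None = None,
    names: Sequence[str] | None = None,
) -> RasterStack:
    """Read aligned single-band rasters into a stack, optionally cropping.

    Layer names default to the file stems (upper-cased).  All layers must
    share one grid after cropping; a mismatch raises :class:`AlignmentError`
    naming the offending layer.
    """
    paths = [Path(p) for p in paths]
    if names is None:
        names = [p.stem.upper() for p in paths]
    layers: list[Layer] = []
    grid: GridSpec | None = None
    for name, p in zip(names, paths):
        g, v, m = read_raster(p)
        if grid is None:
            grid = g
        elif not grid.approx_equal(g):
            raise AlignmentError(f"layer {name!r} ({p}) is not aligned with the first layer")
        layers.append(Layer(name, v, m))
    assert grid is not None
    stack = RasterStack(grid, layers)
    if bbox is not None:
        stack = stack.crop(bbox)
    return stack


def write_stack(stack: RasterStack, out_dir: str | Path, fmt: str = "asc") -> list[Path]:
    """Write one raster per layer into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for l in stack.layers:
        p = out_dir / f"{l.name}.{fmt}"
        write_raster(p, stack.grid, l.values, l.mask)
        written.append(p)
    return written


def extract_values(stack: RasterStack, points: Sequence[tuple[float, float]]):
    """Environmental values at point locations.

    Returns ``(values, rows, cols, outside, masked)`` where ``values`` is a
    (points × layers) array (NaN rows for flagged points), ``outside`` marks
    points beyond the extent and ``masked`` points falling in nodata cells.
    Flagged points are reported, never silently dropped.
    """
    n = len(points)
    p = len(stack.layers)
    values = np.full((n, p), np.nan)
    rows = np.full(n, -1, dtype=int)
    cols = np.full(n, -1, dtype=int)
    outside = np.zeros(n, dtype=bool)
    masked = np.zeros(n, dtype=bool)
    union_mask = stack.mask
    for i, (lon, lat) in enumerate(points):
        r, c = stack.grid.rowcol(lon, lat)
        if r < 0:
            outside[i] = True
            continue
        rows[i], cols[i] = r, c
        if union_mask[r, c]:
            masked[i] = True
            continue
        values[i] = [l.values[r, c] for l in stack.layers]
    return values, rows, cols, outside, masked
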