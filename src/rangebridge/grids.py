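"""Shared reference grids, utilization-distribution rasters, isopleth
extraction, area/perimeter/complexity metrics, and region overlap.

All estimators in this package discretize onto one common ``GridSpec`` so
that AUC and area comparisons between methods are made on the same grid and
extent.  Isopleths are cell sets (not smoothed vector contours): the q%
isopleth is the smallest-mass set of cells holding at least q% of the UD,
and perimeter is the rasterized boundary length under 4-neighborhood
adjacency.  Complexity follows the movement-ecology convention
perimeter (m) / area (ha).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .telemetry import ConfigurationError, Track

M2_PER_HA = 10_000.0


class GridError(ValueError):
    """Grid mismatch or extent failure."""


class DegenerateDataError(ValueError):
    """Input carries no usable signal (all-zero UD, empty region ...)."""


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned raster grid: lower-left origin in meters, square cells.

    Row 0 is the bottom row (southernmost); col 0 is the leftmost column.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ConfigurationError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """(row, col) of the cell containing (x, y); may lie off-grid."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y + (row + 0.5) * self.cell_size,
        )

    def cell_box(self, row: int, col: int):
        x0 = self.origin_x + col * self.cell_size
        y0 = self.origin_y + row * self.cell_size
        return box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)


def make_reference_grid(
    tracks: Sequence[Track], cell_size: float, buffer: float
) -> GridSpec:
    """Grid covering the joint bounding box of all tracks, expanded by
    *buffer* on every side, origin snapped down to a multiple of cell_size."""
    if cell_size <= 0:
        raise ConfigurationError("cell_size must be positive")
    if not tracks or sum(len(t) for t in tracks) < 1:
        raise ConfigurationError("need at least one relocation to build a grid")
    xy = np.vstack([t.xy for t in tracks])
    xmin, ymin = xy.min(axis=0) - buffer
    xmax, ymax = xy.max(axis=0) + buffer
    ox = math.floor(xmin / cell_size) * cell_size
    oy = math.floor(ymin / cell_size) * cell_size
    n_cols = max(1, math.ceil((xmax - ox) / cell_size))
    n_rows = max(1, math.ceil((ymax - oy) / cell_size))
    return GridSpec(ox, oy, cell_size, n_cols, n_rows)


@dataclass(frozen=True)
class UDRaster:
    """Normalized utilization distribution: cell masses summing to 1."""

    grid: GridSpec
    cell_mass: np.ndarray  # (n_rows, n_cols)

    def __post_init__(self) -> None:
        m = np.asarray(self.cell_mass, dtype=float)
        if m.shape != self.grid.shape:
            raise GridError("cell_mass shape does not match grid")
        if (m < 0).any():
            raise DegenerateDataError("UD has negative cell mass")
        if abs(m.sum() - 1.0) > 1e-6:
            raise DegenerateDataError(f"UD mass {m.sum():.8f} != 1")
        object.__setattr__(self, "cell_mass", m)

    @property
    def total_mass(self) -> float:
        return float(self.cell_mass.sum())


@dataclass(frozen=True)
class HabitatRaster:
    """Categorical landscape raster: integer code per cell plus a legend."""

    grid: GridSpec
    codes: np.ndarray  # (n_rows, n_cols) int
    legend: Mapping[int, str]

    def __post_init__(self) -> None:
        c = np.asarray(self.codes)
        if c.shape != self.grid.shape:
            raise GridError("codes shape does not match grid")
        missing = set(np.unique(c).tolist()) - set(self.legend)
        if missing:
            raise ConfigurationError(f"legend lacks codes {sorted(missing)}")
        object.__setattr__(self, "codes", c.astype(int))

    def category_at(self, x: float, y: float) -> str:
        """Habitat name at a point; 'unknown' when off-grid."""
        row, col = self.grid.cell_of(x, y)
        if not (0 <= row < self.grid.n_rows and 0 <= col < self.grid.n_cols):
            return "unknown"
        return self.legend[int(self.codes[row, col])]


# ---------------------------------------------------------------------------
# Isopleths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsoplethRegion:
    """Smallest-mass cell set whose cumulative UD mass reaches ``level``."""

    level: float
    cells: frozenset[tuple[int, int]]
    grid: GridSpec
    mass: float
    area_ha: float = field(init=False)
    perimeter_m: float = field(init=False)
    complexity: float = field(init=False)

    def __post_init__(self) -> None:
        area, perim, cplx = region_metrics_from_cells(self.cells, self.grid)
        object.__setattr__(self, "area_ha", area)
        object.__setattr__(self, "perimeter_m", perim)
        object.__setattr__(self, "complexity", cplx)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid.shape, dtype=bool)
        if self.cells:
            rows, cols = zip(*self.cells)
            m[list(rows), list(cols)] = True
        return m


def isopleth_region(ud: UDRaster, level: float) -> IsoplethRegion:
    """Greedy volume contour: include cells by descending mass until the
    cumulative mass first reaches ``level``.

    Ties at the inclusion boundary are broken by (row, col) lexicographic
    order; zero-mass cells are never included.
    """
    if not (0.0 < level < 1.0):
        raise ConfigurationError("isopleth level must be in (0, 1)")
    m = ud.cell_mass
    if m.max() <= 0:
        raise DegenerateDataError("all-zero UD has no isopleths")
    rows, cols = np.divmod(np.arange(m.size), m.shape[1])
    order = np.lexsort((cols, rows, -m.ravel()))
    masses = m.ravel()[order]
    cum = np.cumsum(masses)
    k = int(np.searchsorted(cum, level - 1e-12)) + 1
    k = min(k, int((masses > 0).sum()))  # never include zero-mass cells
    chosen = order[:k]
    cells = frozenset(zip(rows[chosen].tolist(), cols[chosen].tolist()))
    return IsoplethRegion(level, cells, ud.grid, mass=float(cum[k - 1]))


def region_metrics_from_cells(
    cells: Iterable[tuple[int, int]], grid: GridSpec
) -> tuple[float, float, float]:
    """(area_ha, perimeter_m, complexity) for a raster cell set.

    Perimeter counts every 4-neighborhood cell edge adjacent to a non-member
    (the raster boundary counts); complexity = perimeter_m / area_ha.
    """
    cells = set(cells)
    if not cells:
        raise DegenerateDataError("empty region has no metrics")
    cs = grid.cell_size
    area_ha = len(cells) * cs * cs / M2_PER_HA
    exposed = 0
    for r, c in cells:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (r + dr, c + dc) not in cells:
                exposed += 1
    perimeter_m = exposed * cs
    return area_ha, perimeter_m, perimeter_m / area_ha


def region_metrics(region: IsoplethRegion, grid: GridSpec | None = None):
    """(area_ha, perimeter_m, complexity) of an isopleth region."""
    g = grid or region.grid
    return region_metrics_from_cells(region.cells, g)


def region_overlap(
    a: IsoplethRegion, b: IsoplethRegion
) -> tuple[float, float, float]:
    """(jaccard, fraction_of_a_in_b, fraction_of_b_in_a) as cell-set ratios."""
    if a.grid != b.grid:
        raise GridError("regions live on different grids")
    if not a.cells or not b.cells:
        raise DegenerateDataError("overlap of an empty region is undefined")
    inter = len(a.cells & b.cells)
    union = len(a.cells | b.cells)
    return (inter / union, inter / len(a.cells), inter / len(b.cells))


# ---------------------------------------------------------------------------
# Plain-text raster and vector I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray) -> None:
    """Write a raster as an ESRI ASCII grid (plain text, row 0 printed last
    so the file reads north-to-south as the format requires)."""
    v = np.asarray(values)
    if v.shape != grid.shape:
        raise GridError("values shape does not match grid")
    header = (
        f"ncols {grid.n_cols}\nnrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x:.6f}\nyllcorner {grid.origin_y:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in v[::-1]:
            fh.write(" ".join(format(x, ".10g") for x in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    with open(path) as fh:
        head = {}
        for _ in range(6):
            k, val = fh.readline().split()
            head[k.lower()] = float(val)
        rows = [np.fromstring(line, sep=" ") for line in fh if line.strip()]
    grid = GridSpec(
        head["xllcorner"],
        head["yllcorner"],
        head["cellsize"],
        int(head["ncols"]),
        int(head["nrows"]),
    )
    return grid, np.vstack(rows)[::-1]


def region_to_geojson_feature(
    region: IsoplethRegion, properties: dict | None = None
) -> dict:
    """Union of cell squares as one GeoJSON (multi)polygon feature."""
    geom = unary_union([region.grid.cell_box(r, c) for r, c in region.cells])
    props = {"level": region.level, "area_ha": region.area_ha,
             "perimeter_m": region.perimeter_m, "complexity": region.complexity}
    props.update(properties or {})
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


def write_geojson(path: str | Path, features: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def region_metrics_table(
    regions: Mapping[tuple, IsoplethRegion]
) -> pd.DataFrame:
    """Metric table keyed by arbitrary tuple keys (animal, method, level...)."""
    rows = []
    for key, reg in regions.items():
        rows.append(
            dict(
                key=" × ".join(map(str, key)),
                level=reg.level,
                n_cells=len(reg.cells),
                area_ha=reg.area_ha,
                perimeter_m=reg.perimeter_m,
                complexity=reg.complexity,
            )
        )
    return pd.DataFrame(rows)
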