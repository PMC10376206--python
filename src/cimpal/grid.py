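"""Analysis lattice: a regular lat/lon grid with half-open cell semantics.

The study area is partitioned into square cells of a fixed angular
resolution (0.01 degrees by default, roughly 1 km at Mediterranean
latitudes). Cells are indexed row-major from the northwest corner: row 0
is the northernmost row, column 0 the westernmost column. Cell boundaries
are half-open on their east and south edges, so a point lying exactly on
an interior edge belongs to the east/south neighbour; the last row and
column are closed so the full extent maps onto the grid.

Cell areas are treated as equal (pure degree-space arithmetic). All
downstream statistics count cells, not square kilometres, so no geodesic
correction is applied anywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Relative tolerance used to snap coordinates onto cell boundaries and to
#: decide whether an extent spans an integer number of cells.
SNAP_TOL = 1e-9


class OutOfGridError(ValueError):
    """A coordinate falls outside the grid extent."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis lattice.

    Attributes
    ----------
    lon_min, lat_min, lon_max, lat_max:
        Bounding coordinates in decimal degrees; ``lon_max > lon_min`` and
        ``lat_max > lat_min``.
    resolution:
        Cell edge length in degrees.
    n_rows, n_cols:
        Lattice shape; ``n_cols * resolution`` spans the longitude extent
        exactly (likewise for rows).
    """

    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float
    resolution: float
    n_rows: int
    n_cols: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def row_lats(self) -> np.ndarray:
        """Cell-centroid latitudes, row 0 (north) first."""
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.resolution

    def col_lons(self) -> np.ndarray:
        """Cell-centroid longitudes, column 0 (west) first."""
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of one cell."""
        lon0 = self.lon_min + col * self.resolution
        lat1 = self.lat_max - row * self.resolution
        return (lon0, lat1 - self.resolution, lon0 + self.resolution, lat1)

    def contains(self, lon, lat):
        """Element-wise test that points lie inside the (closed) extent."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )


def build_grid(
    extent: tuple[float, float, float, float], resolution: float = 0.01
) -> GridSpec:
    """Build the analysis grid covering ``extent``.

    Parameters
    ----------
    extent:
        ``(lon_min, lat_min, lon_max, lat_max)`` in decimal degrees.
    resolution:
        Cell size in degrees (default 0.01).

    If the extent does not span an integer number of cells (to relative
    tolerance ``SNAP_TOL``) it is expanded outward — the eastern and
    northern edges move to the next cell boundary, anchored at
    ``(lon_min, lat_min)``.
    """
    lon_min, lat_min, lon_max, lat_max = (float(v) for v in extent)
    if not all(math.isfinite(v) for v in (lon_min, lat_min, lon_max, lat_max)):
        raise ValueError("extent coordinates must be finite")
    if not (resolution > 0 and math.isfinite(resolution)):
        raise ValueError(f"resolution must be positive and finite, got {resolution}")
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("degenerate extent: max must exceed min on both axes")

    def _n_cells(span: float) -> int:
        q = span / resolution
        n = round(q)
        if abs(q - n) > SNAP_TOL * max(1.0, abs(q)) or n == 0:
            n = math.ceil(q)
        return int(n)

    n_cols = _n_cells(lon_max - lon_min)
    n_rows = _n_cells(lat_max - lat_min)
    return GridSpec(
        lon_min=lon_min,
        lat_min=lat_min,
        lon_max=lon_min + n_cols * resolution,
        lat_max=lat_min + n_rows * resolution,
        resolution=resolution,
        n_rows=n_rows,
        n_cols=n_cols,
    )


def _axis_index(offset, resolution: float, n: int) -> np.ndarray:
    """Floor offset/resolution with boundary snapping; clamp the closed end."""
    q = np.asarray(offset, dtype=float) / resolution
    nearest = np.round(q)
    q = np.where(np.abs(q - nearest) <= SNAP_TOL * np.maximum(1.0, np.abs(q)), nearest, q)
    idx = np.floor(q).astype(np.int64)
    # last row/column is closed on its far edge
    idx[idx == n] = n - 1
    return idx


def cells_of(lon, lat, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised point-to-cell assignment.

    Points must lie inside the grid extent (boundary included); a point on
    an interior shared edge is assigned to the east/south neighbour.
    Raises :class:`OutOfGridError` if any point falls outside.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    inside = grid.contains(lon, lat)
    if not np.all(inside):
        bad = np.argwhere(~inside)[0][0]
        raise OutOfGridError(
            f"point (lon={lon[bad]}, lat={lat[bad]}) outside grid extent "
            f"[{grid.lon_min}, {grid.lon_max}] x [{grid.lat_min}, {grid.lat_max}]"
        )
    col = _axis_index(lon - grid.lon_min, grid.resolution, grid.n_cols)
    row = _axis_index(grid.lat_max - lat, grid.resolution, grid.n_rows)
    return row, col


def cell_of(lon: float, lat: float, grid: GridSpec) -> tuple[int, int]:
    """Scalar convenience wrapper around :func:`cells_of`."""
    row, col = cells_of([lon], [lat], grid)
    return int(row[0]), int(col[0])


@dataclass(frozen=True)
class RegionPartition:
    """North/South split of the masked cells at a boundary latitude.

    A cell is *south* iff its centroid latitude is strictly below
    ``boundary_latitude``. ``south`` is defined on the full lattice;
    counts refer to masked cells only.
    """

    boundary_latitude: float
    south: np.ndarray  # bool, grid shape
    mask: np.ndarray  # bool, grid shape
    n_north: int
    n_south: int

    def labels(self) -> np.ndarray:
        """Per-cell string labels ('north'/'south'), full lattice."""
        return np.where(self.south, "south", "north")


def partition_regions(
    grid: GridSpec, mask: np.ndarray, boundary_latitude: float
) -> RegionPartition:
    """Label every masked cell north or south of ``boundary_latitude``.

    A boundary outside the grid extent yields a degenerate but valid
    partition (all cells on one side).
    """
    if not math.isfinite(boundary_latitude):
        raise ValueError("boundary_latitude must be finite")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    south = np.broadcast_to(
        (grid.row_lats() < boundary_latitude)[:, None], grid.shape
    ).copy()
    n_south = int(np.count_nonzero(south & mask))
    n_north = int(np.count_nonzero(mask)) - n_south
    return RegionPartition(
        boundary_latitude=float(boundary_latitude),
        south=south,
        mask=mask,
        n_north=n_north,
        n_south=n_south,
    )
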