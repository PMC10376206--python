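"""Habitat catalog and polygon-to-grid fractional cover rasterization.

Ten broad marine habitat types are tracked: nine benthic (seagrass
meadows; soft and hard substrates split by depth class 0-60 m, 60-200 m
and >200 m; submarine caves; coralligenous formations) plus the pelagic
water column. Habitats at 0-200 m depth count as *coastal*, those deeper
than 200 m as *open sea*; the pelagic habitat belongs to both zones and
covers every study-area cell with full cover.

Per-cell cover of a benthic habitat is the fraction of the cell's area
occupied by that habitat's (unioned) polygons, computed in degree space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec

DEPTH_CLASSES = ("shallow_0_60", "deep_60_200", "dysphotic_gt200", "water_column")
SUBSTRATES = ("hard", "soft", "seagrass", "cave", "coralligenous", "pelagic")
ZONES = ("coastal", "open_sea", "both")

#: Benthic covers in one cell may exceed 1 by at most this before a
#: consistency warning is raised (real habitat maps can overlap).
BENTHIC_SUM_TOL = 1e-6


def zone_for_depth_class(depth_class: str) -> str:
    if depth_class in ("shallow_0_60", "deep_60_200"):
        return "coastal"
    if depth_class == "dysphotic_gt200":
        return "open_sea"
    if depth_class == "water_column":
        return "both"
    raise ValueError(f"unknown depth class {depth_class!r}")


@dataclass(frozen=True)
class HabitatType:
    habitat_id: str
    name: str
    depth_class: str
    substrate: str

    def __post_init__(self):
        if self.depth_class not in DEPTH_CLASSES:
            raise ValueError(f"unknown depth class {self.depth_class!r}")
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"unknown substrate {self.substrate!r}")

    @property
    def zone(self) -> str:
        """Coastal / open-sea / both, fixed by the depth class."""
        return zone_for_depth_class(self.depth_class)

    @property
    def is_pelagic(self) -> bool:
        return self.depth_class == "water_column"


def default_catalog() -> dict[str, HabitatType]:
    """The ten-habitat catalog used throughout the analysis."""
    types = [
        HabitatType("seagrass", "Seagrass meadows", "shallow_0_60", "seagrass"),
        HabitatType("shallow_soft", "Shallow soft substrates (0-60 m)", "shallow_0_60", "soft"),
        HabitatType("deep_soft", "Deep soft substrates (60-200 m)", "deep_60_200", "soft"),
        HabitatType("dysphotic_soft", "Soft substrates of the dysphotic zone (>200 m)", "dysphotic_gt200", "soft"),
        HabitatType("shallow_hard", "Shallow hard substrates (0-60 m)", "shallow_0_60", "hard"),
        HabitatType("deep_hard", "Deep hard substrates (60-200 m)", "deep_60_200", "hard"),
        HabitatType("dysphotic_hard", "Hard substrates of the dysphotic zone (>200 m)", "dysphotic_gt200", "hard"),
        HabitatType("caves", "Submarine caves", "shallow_0_60", "cave"),
        HabitatType("coralligenous", "Coralligenous formations", "deep_60_200", "coralligenous"),
        HabitatType("pelagic", "Pelagic habitat", "water_column", "pelagic"),
    ]
    return {t.habitat_id: t for t in types}


PELAGIC_ID = "pelagic"


@dataclass
class HabitatCoverStack:
    """Per-habitat fractional cover layers on a common grid.

    ``covers[habitat_id]`` holds the in-[0,1] cover fraction per cell;
    cells outside ``study_mask`` carry zero cover. The pelagic layer is 1
    on every masked cell.
    """

    grid: GridSpec
    covers: dict[str, np.ndarray]
    study_mask: np.ndarray
    catalog: dict[str, HabitatType] = field(default_factory=default_catalog)

    def benthic_ids(self) -> list[str]:
        return [h for h in self.covers if not self.catalog[h].is_pelagic]

    def benthic_sum(self) -> np.ndarray:
        """Per-cell total benthic cover (pelagic excluded)."""
        out = np.zeros(self.grid.shape)
        for h in self.benthic_ids():
            out += self.covers[h]
        return out

    def validate(self) -> list[str]:
        """Check the stack invariants; returns human-readable problems."""
        problems: list[str] = []
        mask = np.asarray(self.study_mask, dtype=bool)
        if mask.shape != self.grid.shape:
            problems.append("study_mask shape does not match grid")
            return problems
        for h, cov in self.covers.items():
            if h not in self.catalog:
                problems.append(f"habitat {h!r} missing from catalog")
            if cov.shape != self.grid.shape:
                problems.append(f"cover layer {h!r} shape mismatch")
                continue
            if np.any(cov < -1e-12) or np.any(cov > 1 + 1e-12):
                problems.append(f"cover layer {h!r} outside [0, 1]")
            if np.any(cov[~mask] != 0):
                problems.append(f"cover layer {h!r} nonzero outside study mask")
        if np.any(self.benthic_sum() > 1 + BENTHIC_SUM_TOL):
            problems.append("benthic covers sum to more than 1 in some cells")
        if PELAGIC_ID in self.covers and np.any(self.covers[PELAGIC_ID][mask] != 1.0):
            problems.append("pelagic cover is not 1 on all masked cells")
        return problems


def _cell_boxes(grid: GridSpec, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    res = grid.resolution
    x0 = grid.lon_min + cols * res
    y1 = grid.lat_max - rows * res
    return shapely.box(x0, y1 - res, x0 + res, y1)


def _cells_in_bbox(grid: GridSpec, geom: BaseGeometry):
    """Row/col index arrays of all cells whose box overlaps geom's bbox."""
    minx, miny, maxx, maxy = geom.bounds
    res = grid.resolution
    c0 = max(0, int(np.floor((minx - grid.lon_min) / res)))
    c1 = min(grid.n_cols, int(np.ceil((maxx - grid.lon_min) / res)))
    r0 = max(0, int(np.floor((grid.lat_max - maxy) / res)))
    r1 = min(grid.n_rows, int(np.ceil((grid.lat_max - miny) / res)))
    if c1 <= c0 or r1 <= r0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    return rows.ravel(), cols.ravel()


def _fraction_layer(grid: GridSpec, geom: BaseGeometry) -> np.ndarray:
    """Per-cell area fraction occupied by geom, degree-space arithmetic."""
    layer = np.zeros(grid.shape)
    if geom.is_empty:
        return layer
    rows, cols = _cells_in_bbox(grid, geom)
    if rows.size == 0:
        return layer
    boxes = _cell_boxes(grid, rows, cols)
    areas = shapely.area(shapely.intersection(boxes, geom))
    layer[rows, cols] = areas / (grid.resolution**2)
    return layer


def rasterize_covers(
    polygons: list[tuple[str, BaseGeometry]],
    grid: GridSpec,
    study_area: BaseGeometry | None = None,
    mask_rule: str = "intersect",
    catalog: dict[str, HabitatType] | None = None,
    repair: bool = True,
) -> HabitatCoverStack:
    """Convert tagged habitat polygons into a fractional-cover stack.

    Parameters
    ----------
    polygons:
        ``(habitat_id, geometry)`` pairs; multiple polygons per habitat
        are unioned before intersection so overlaps within one habitat
        are never double counted.
    study_area:
        Optional polygon delimiting the analysis domain. ``mask_rule``
        selects whether cells merely intersecting it ("intersect") or
        fully inside it ("within") are masked in. Without it every grid
        cell is in the study area.
    repair:
        Repair invalid (self-intersecting) polygons with ``make_valid``;
        when False invalid geometry raises.

    The pelagic layer is forced to full cover on every masked cell.
    Declared habitats without polygons get a zero layer with a warning.
    """
    catalog = catalog if catalog is not None else default_catalog()
    if mask_rule not in ("intersect", "within"):
        raise ValueError(f"unknown mask_rule {mask_rule!r}")

    by_habitat: dict[str, list[BaseGeometry]] = {}
    for habitat_id, geom in polygons:
        if habitat_id not in catalog:
            raise KeyError(f"unknown habitat_id {habitat_id!r}")
        if not geom.is_valid:
            if not repair:
                raise ValueError(f"invalid polygon for habitat {habitat_id!r}")
            geom = shapely.make_valid(geom)
        by_habitat.setdefault(habitat_id, []).append(geom)

    # study mask
    if study_area is None:
        mask = np.ones(grid.shape, dtype=bool)
    else:
        if not study_area.is_valid:
            study_area = shapely.make_valid(study_area)
        if mask_rule == "intersect":
            frac = _fraction_layer(grid, study_area)
            # epsilon guards against slivers from boundary-touching geometry
            mask = frac > 1e-12
        else:  # within
            rows, cols = _cells_in_bbox(grid, study_area)
            mask = np.zeros(grid.shape, dtype=bool)
            if rows.size:
                boxes = _cell_boxes(grid, rows, cols)
                mask[rows, cols] = shapely.covered_by(boxes, study_area)

    covers: dict[str, np.ndarray] = {}
    for habitat_id, ht in catalog.items():
        if ht.is_pelagic:
            continue
        geoms = by_habitat.get(habitat_id)
        if not geoms:
            covers[habitat_id] = np.zeros(grid.shape)
            continue
        layer = _fraction_layer(grid, shapely.union_all(geoms))
        layer[~mask] = 0.0
        # drop sub-epsilon slivers (fp noise from polygon unions), which
        # would otherwise inflate habitat support counts
        layer[layer < 1e-12] = 0.0
        covers[habitat_id] = np.clip(layer, 0.0, 1.0)

    missing = [h for h in catalog if h not in by_habitat and h != PELAGIC_ID]
    if missing:
        warnings.warn(
            f"no polygons supplied for habitats {missing}; zero cover layers",
            stacklevel=2,
        )

    pelagic = np.zeros(grid.shape)
    pelagic[mask] = 1.0
    covers[PELAGIC_ID] = pelagic

    stack = HabitatCoverStack(grid=grid, covers=covers, study_mask=mask, catalog=catalog)
    if np.any(stack.benthic_sum() > 1 + BENTHIC_SUM_TOL):
        warnings.warn(
            "benthic habitat covers exceed 1 in some cells (overlapping habitat maps)",
            stacklevel=2,
        )
    return stack
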