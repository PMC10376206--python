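"""Seeded synthetic seascapes for end-to-end pipeline testing.

The study's real inputs (occurrence databases, habitat maps, suitability
models) are not redistributable, so this module generates gridded
seascapes with the statistical structure the analysis consumes:

* a smooth synthetic bathymetry with a monotonic offshore (west-to-east)
  depth gradient plus seeded noise, which stratifies cells into the
  shallow (0-60 m), deep (60-200 m) and dysphotic (>200 m) classes;
* benthic habitats grown as contiguous patches inside their depth class
  until per-habitat target fractions of the seabed are met — patches are
  mutually exclusive, so per-cell benthic covers sum to at most 1;
* spatially clustered occurrence records: a Poisson count per in-range
  cell whose mean is boosted by ``south_bias`` in the southern region,
  with positions uniform within the cell;
* smooth suitability surfaces: an isotropic Gaussian kernel around a
  planted center, multiplied by a south-bias ramp and clipped to [0, 1];
* evidence tables with a planted impact ordering — one designated
  "worst" species gets the top magnitude class in every habitat it
  impacts (and the widest planted range), giving a ground truth the
  ranking indicators must recover.

Every output is a pure function of (config, seed). The Poisson/Gaussian
choices are the simplest processes with controllable intensity and
smoothness; no attempt is made to replicate real coastlines or species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import GridSpec, RegionPartition, build_grid, partition_regions
from .habitats import (
    PELAGIC_ID,
    HabitatCoverStack,
    default_catalog,
)
from .weights import EvidenceEntry

# rng substream tags, one per generator stage
_RNG_SEASCAPE, _RNG_SPECIES, _RNG_RECORDS, _RNG_EVIDENCE = range(4)

#: depth (m) separating the shallow/deep/dysphotic benthic classes
DEPTH_BREAKS = (60.0, 200.0)


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Defaults describe a 0.5 x 0.5 degree seascape at the analysis
    resolution of 0.01 degrees (2500 cells), six species split evenly
    over the three biotic groups, and a seabed mosaic whose benthic
    target fractions sum to under one half of the masked cells. The
    ``south_bias`` multiplier scales record intensity and the
    suitability ramp in the southern region; the south-hotspot preset
    uses 4, matching a fourfold North-South contrast.
    """

    seed: int = 0
    extent: tuple[float, float, float, float] = (25.0, 36.0, 25.5, 36.5)
    resolution: float = 0.01
    n_species: dict[str, int] = field(
        default_factory=lambda: {"invertebrates": 2, "macrophytes": 2, "fish": 2}
    )
    record_intensity: float = 0.5  # expected records per in-range cell
    south_bias: float = 1.0
    habitat_targets: dict[str, float] = field(
        default_factory=lambda: {
            "shallow_hard": 0.05,
            "shallow_soft": 0.10,
            "seagrass": 0.03,
            "deep_hard": 0.04,
            "deep_soft": 0.10,
            "dysphotic_soft": 0.15,
        }
    )
    patch_size: int = 40  # target patch extent, in cells
    suitability_radius: float = 0.12  # Gaussian sigma, degrees
    range_radius: float = 0.15  # planted occurrence-range disc radius, degrees
    magnitude_pool: tuple[str, ...] = ("minimal", "minor", "moderate", "major", "massive")
    evidence_pool: tuple[str, ...] = ("weak", "moderate", "strong")
    d4_threshold: float = 0.1
    high_score_threshold: float = 8.0
    boundary_latitude: float | None = None  # None -> grid midline
    plant_south: bool = False  # plant species centers in the southern half

    def validate(self) -> None:
        catalog = default_catalog()
        unknown = [h for h in self.habitat_targets if h not in catalog]
        if unknown:
            raise ValueError(f"unknown habitats in targets: {unknown}")
        if PELAGIC_ID in self.habitat_targets:
            raise ValueError("pelagic cover is implicit; do not set a target for it")
        total = sum(self.habitat_targets.values())
        if total > 1 + 1e-9:
            raise ValueError(f"benthic habitat targets sum to {total} > 1")
        if any(f < 0 for f in self.habitat_targets.values()):
            raise ValueError("habitat targets must be non-negative")
        if self.record_intensity < 0 or self.south_bias < 0:
            raise ValueError("intensities must be non-negative")
        if not self.magnitude_pool or not self.evidence_pool:
            raise ValueError("class pools must be non-empty")

    def to_dict(self) -> dict:
        return asdict(self)


def preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Named scenario presets.

    * ``south_hotspot`` — fourfold southern bias with species planted in
      the south, mimicking a North-South impact contrast;
    * ``uniform`` — no regional bias, species planted anywhere;
    * ``empty`` — no species at all (all-zero scores downstream).
    """
    if name == "south_hotspot":
        return ScenarioConfig(seed=seed, south_bias=4.0, plant_south=True)
    if name == "uniform":
        return ScenarioConfig(seed=seed, south_bias=1.0, plant_south=False)
    if name == "empty":
        return ScenarioConfig(
            seed=seed,
            n_species={"invertebrates": 0, "macrophytes": 0, "fish": 0},
            south_bias=1.0,
        )
    raise ValueError(f"unknown preset {name!r}")


@dataclass
class Seascape:
    grid: GridSpec
    stack: HabitatCoverStack
    partition: RegionPartition
    depth: np.ndarray  # metres, positive down

    @property
    def mask(self) -> np.ndarray:
        return self.stack.study_mask


def _depth_field(cfg: ScenarioConfig, grid: GridSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth monotone-offshore bathymetry with seeded noise (metres)."""
    t = (grid.col_lons() - grid.lon_min) / (grid.lon_max - grid.lon_min)
    base = 300.0 * np.power(t, 1.5)
    noise = gaussian_filter(rng.standard_normal(grid.shape), sigma=3.0) * 25.0
    return np.clip(base[None, :] + noise, 0.1, None)


def _grow_patches(
    eligible: np.ndarray,
    target_n: int,
    patch_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign ``target_n`` cells from ``eligible`` as contiguous patches.

    Patches grow by randomized breadth-first flood fill from random seed
    cells; growth stops per patch at ``patch_size`` cells or when the
    patch runs out of eligible neighbours.
    """
    n_rows, n_cols = eligible.shape
    assigned = np.zeros_like(eligible, dtype=bool)
    available = eligible.copy()
    n_assigned = 0
    while n_assigned < target_n and available.any():
        seeds = np.argwhere(available)
        r0, c0 = seeds[rng.integers(len(seeds))]
        frontier = [(int(r0), int(c0))]
        available[r0, c0] = False
        patch_n = 0
        while frontier and patch_n < patch_size and n_assigned < target_n:
            idx = rng.integers(len(frontier))
            r, c = frontier.pop(int(idx))
            assigned[r, c] = True
            patch_n += 1
            n_assigned += 1
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols and available[rr, cc]:
                    available[rr, cc] = False
                    frontier.append((rr, cc))
    return assigned


def gen_seascape(cfg: ScenarioConfig) -> Seascape:
    """Generate the study mask, habitat cover stack and region split."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, _RNG_SEASCAPE])
    grid = build_grid(cfg.extent, cfg.resolution)
    mask = np.ones(grid.shape, dtype=bool)
    depth = _depth_field(cfg, grid, rng)

    shallow = depth <= DEPTH_BREAKS[0]
    deep = (depth > DEPTH_BREAKS[0]) & (depth <= DEPTH_BREAKS[1])
    dysphotic = depth > DEPTH_BREAKS[1]
    class_masks = {
        "shallow_0_60": shallow,
        "deep_60_200": deep,
        "dysphotic_gt200": dysphotic,
    }

    catalog = default_catalog()
    n_masked = int(mask.sum())
    taken = np.zeros(grid.shape, dtype=bool)
    covers: dict[str, np.ndarray] = {}
    for habitat_id in catalog:
        if habitat_id == PELAGIC_ID:
            continue
        frac = cfg.habitat_targets.get(habitat_id, 0.0)
        layer = np.zeros(grid.shape)
        if frac > 0:
            eligible = class_masks[catalog[habitat_id].depth_class] & mask & ~taken
            target_n = int(round(frac * n_masked))
            patch = _grow_patches(eligible, target_n, cfg.patch_size, rng)
            taken |= patch
            layer[patch] = 1.0
            # fractional cover on patch rims keeps percent-cover semantics honest
            interior = patch.copy()
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                shifted = np.zeros_like(patch)
                src = patch[
                    max(dr, 0) : patch.shape[0] + min(dr, 0),
                    max(dc, 0) : patch.shape[1] + min(dc, 0),
                ]
                shifted[
                    max(-dr, 0) : patch.shape[0] + min(-dr, 0),
                    max(-dc, 0) : patch.shape[1] + min(-dc, 0),
                ] = src
                interior &= shifted
            layer[patch & ~interior] = 0.7
        covers[habitat_id] = layer

    pelagic = np.zeros(grid.shape)
    pelagic[mask] = 1.0
    covers[PELAGIC_ID] = pelagic

    stack = HabitatCoverStack(grid=grid, covers=covers, study_mask=mask, catalog=catalog)
    boundary = (
        cfg.boundary_latitude
        if cfg.boundary_latitude is not None
        else 0.5 * (grid.lat_min + grid.lat_max)
    )
    partition = partition_regions(grid, mask, boundary)
    return Seascape(grid=grid, stack=stack, partition=partition, depth=depth)


def disc_range(grid: GridSpec, center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean cell mask of a disc (degrees) around ``center``."""
    lon_c, lat_c = center
    lons = grid.col_lons()[None, :]
    lats = grid.row_lats()[:, None]
    return (lons - lon_c) ** 2 + (lats - lat_c) ** 2 <= radius**2


def band_range(grid: GridSpec, lat_lo: float, lat_hi: float) -> np.ndarray:
    """Boolean cell mask of a latitude band (centroid-based)."""
    lats = grid.row_lats()
    in_band = (lats >= lat_lo) & (lats < lat_hi)
    return np.broadcast_to(in_band[:, None], grid.shape).copy()


def gen_records(
    cfg: ScenarioConfig,
    seascape: Seascape,
    ranges: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Draw clustered occurrence records inside each species' range.

    Per in-range masked cell the record count is Poisson with mean
    ``record_intensity`` (times ``south_bias`` in the southern region);
    record positions are uniform within their cell, respecting the
    half-open cell convention.
    """
    rng = np.random.default_rng([cfg.seed, _RNG_RECORDS])
    grid = seascape.grid
    res = grid.resolution
    rows: list[tuple[str, float, float]] = []
    for species_id in sorted(ranges):
        cells = np.asarray(ranges[species_id], dtype=bool) & seascape.mask
        if not cells.any():
            warnings.warn(
                f"empty planted range for {species_id!r}; zero records", stacklevel=2
            )
            continue
        rr, cc = np.nonzero(cells)
        lam = np.full(rr.shape, cfg.record_intensity)
        lam[seascape.partition.south[rr, cc]] *= cfg.south_bias
        counts = rng.poisson(lam)
        for r, c, k in zip(rr, cc, counts):
            if k == 0:
                continue
            u = rng.random(k)
            v = rng.random(k)
            lon0 = grid.lon_min + c * res
            lat1 = grid.lat_max - r * res
            for ui, vi in zip(u, v):
                rows.append((species_id, lon0 + ui * res, lat1 - vi * res))
    return pd.DataFrame(rows, columns=["species", "lon", "lat"])


def gen_suitability(
    cfg: ScenarioConfig,
    seascape: Seascape,
    center: tuple[float, float],
    radius: float | None = None,
) -> np.ndarray:
    """Smooth suitability surface around a planted center.

    An isotropic Gaussian kernel (sigma = ``radius``, peak 1 at the
    center) is multiplied by the south-bias ramp — 1 at the northern
    edge rising linearly to ``south_bias`` at the southern edge — and
    clipped to [0, 1].
    """
    grid = seascape.grid
    sigma = radius if radius is not None else cfg.suitability_radius
    lon_c, lat_c = center
    lons = grid.col_lons()[None, :]
    lats = grid.row_lats()[:, None]
    d2 = (lons - lon_c) ** 2 + (lats - lat_c) ** 2
    kernel = np.exp(-d2 / (2.0 * sigma**2))
    southness = (grid.lat_max - lats) / (grid.lat_max - grid.lat_min)
    ramp = 1.0 + (cfg.south_bias - 1.0) * southness
    out = np.clip(kernel * ramp, 0.0, 1.0)
    out[~seascape.mask] = 0.0
    return out


def gen_evidence(
    cfg: ScenarioConfig,
    impacted: dict[str, list[str]],
    worst_species: str | None,
) -> tuple[list[EvidenceEntry], list[str]]:
    """Assign magnitude/evidence classes with a planted impact ordering.

    The designated worst species receives the top magnitude class in
    every habitat it impacts; all other species draw from the pool
    below the top class, so the planted separation is strict. Returns
    the entries plus the ground-truth ordering — species sorted by
    (max magnitude rank, number of impacted habitats), both descending,
    ties lexicographic.
    """
    rng = np.random.default_rng([cfg.seed, _RNG_EVIDENCE])
    top = cfg.magnitude_pool[-1]
    lesser = cfg.magnitude_pool[:-1] or cfg.magnitude_pool
    entries: list[EvidenceEntry] = []
    key: dict[str, tuple[int, int]] = {}
    for species_id in sorted(impacted):
        habitats = impacted[species_id]
        max_rank = 0
        for habitat_id in habitats:
            if species_id == worst_species:
                magnitude = top
            else:
                magnitude = str(rng.choice(lesser))
            evidence = str(rng.choice(cfg.evidence_pool))
            entries.append(EvidenceEntry(species_id, habitat_id, magnitude, evidence))
            max_rank = max(max_rank, cfg.magnitude_pool.index(magnitude) + 1)
        key[species_id] = (max_rank, len(habitats))
    ordering = sorted(key, key=lambda s: (-key[s][0], -key[s][1], s))
    return entries, ordering


@dataclass
class Scenario:
    """A fully generated synthetic study: inputs plus planted ground truth."""

    config: ScenarioConfig
    seascape: Seascape
    species_meta: pd.DataFrame  # species, biotic_group, status
    centers: dict[str, tuple[float, float]]
    ranges: dict[str, np.ndarray]
    records: pd.DataFrame
    suitability: dict[str, np.ndarray]
    evidence: list[EvidenceEntry]
    ground_truth_ordering: list[str]
    worst_species: str | None


def build_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate a complete scenario from one config + seed.

    The first invertebrate (when present) is the designated worst
    species: it impacts the pelagic habitat plus every benthic habitat
    with a positive target, carries the top magnitude class throughout,
    and is planted with the widest range (the whole study area, with a
    broad suitability kernel). Remaining species are planted on discs —
    in the southern half when ``plant_south`` is set.
    """
    cfg.validate()
    seascape = gen_seascape(cfg)
    grid = seascape.grid
    rng = np.random.default_rng([cfg.seed, _RNG_SPECIES])

    benthic_pool = [h for h, f in cfg.habitat_targets.items() if f > 0]
    meta_rows = []
    centers: dict[str, tuple[float, float]] = {}
    ranges: dict[str, np.ndarray] = {}
    impacted: dict[str, list[str]] = {}
    radii: dict[str, float] = {}
    worst: str | None = None

    lat_mid = 0.5 * (grid.lat_min + grid.lat_max)
    for group in ("invertebrates", "macrophytes", "fish"):
        for k in range(cfg.n_species.get(group, 0)):
            species_id = f"{group[:4]}_{k + 1:02d}"
            meta_rows.append(
                {"species": species_id, "biotic_group": group, "status": "alien"}
            )
            if group == "invertebrates" and k == 0:
                # the designated worst species: pelagic + all benthic habitats,
                # study-wide range, broad kernel centered in the south
                worst = species_id
                centers[species_id] = (
                    0.5 * (grid.lon_min + grid.lon_max),
                    grid.lat_min + 0.25 * (grid.lat_max - grid.lat_min),
                )
                radii[species_id] = 0.5 * (grid.lon_max - grid.lon_min)
                ranges[species_id] = seascape.mask.copy()
                impacted[species_id] = [PELAGIC_ID, *benthic_pool]
                continue
            lat_hi = lat_mid if cfg.plant_south else grid.lat_max
            center = (
                rng.uniform(grid.lon_min, grid.lon_max),
                rng.uniform(grid.lat_min, lat_hi),
            )
            centers[species_id] = center
            radii[species_id] = cfg.suitability_radius
            ranges[species_id] = disc_range(grid, center, cfg.range_radius)
            n_hab = int(rng.integers(1, min(3, len(benthic_pool)) + 1))
            habs = list(rng.choice(benthic_pool, size=n_hab, replace=False))
            impacted[species_id] = [str(h) for h in habs]

    species_meta = pd.DataFrame(
        meta_rows, columns=["species", "biotic_group", "status"]
    )
    records = gen_records(cfg, seascape, ranges)
    suitability = {
        sp: gen_suitability(cfg, seascape, centers[sp], radii[sp]) for sp in centers
    }
    evidence, ordering = gen_evidence(cfg, impacted, worst)
    return Scenario(
        config=cfg,
        seascape=seascape,
        species_meta=species_meta,
        centers=centers,
        ranges=ranges,
        records=records,
        suitability=suitability,
        evidence=evidence,
        ground_truth_ordering=ordering,
        worst_species=worst,
    )
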