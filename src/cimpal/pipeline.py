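"""End-to-end orchestration: grid -> covers -> layers -> weights ->
cumulative scores -> disaggregations -> indicators.

Two entry points cover the two ways the analysis is driven:

* :func:`run_pipeline` executes the file-based workflow described by a
  :class:`RunConfig` (GeoJSON habitat polygons, CSV records/evidence,
  GeoTIFF suitability rasters) and writes every product plus a
  machine-readable manifest;
* :func:`run_scenario` runs the identical computation on an in-memory
  synthetic :class:`~cimpal.synthetic.Scenario`.

Both share :func:`analyze`, so file-based and synthetic runs cannot
drift apart.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from . import io as cio
from .core import (
    CimpalMap,
    compute_cimpal,
    group_disaggregation,
    habitat_disaggregation,
    habitat_score_map,
    high_score_frequency,
    zone_masks,
)
from .grid import GridSpec, RegionPartition, build_grid, partition_regions
from .habitats import HabitatCoverStack, default_catalog, rasterize_covers
from .indicators import add_ranks, build_indicator_table
from .species import SpeciesLayer, layer_from_records, layer_from_suitability
from .synthetic import Scenario
from .weights import ImpactWeightTable, WeightMatrix, resolve_weights


class PipelineError(RuntimeError):
    """A hard error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """File-based run description.

    Thresholds default to the published conventions: cells scoring below
    0.1 are excluded from the D4 mean, and the high-score regional
    comparison uses score > 20.
    """

    habitat_geojson: str
    records_csv: str
    evidence_csv: str
    species_metadata_csv: str
    output_dir: str
    extent: tuple[float, float, float, float]
    resolution: float = 0.01
    weight_matrix: str | None = None  # None -> packaged default
    suitability_dir: str | None = None
    d4_threshold: float = 0.1
    high_score_threshold: float = 20.0
    boundary_latitude: float | None = None  # None -> grid midline
    exclude: list[str] = field(default_factory=list)
    a_source: str = "sdm"  # population state: 'sdm' (fallback records) | 'records'
    rescale: str = "none"
    mask_rule: str = "intersect"
    d2_d4_source: str = "sdm"
    cover_weighted_mean: bool = False

    def validate(self) -> None:
        for name in ("habitat_geojson", "records_csv", "evidence_csv", "species_metadata_csv"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.weight_matrix is not None and not Path(self.weight_matrix).exists():
            raise FileNotFoundError(f"weight_matrix path does not exist: {self.weight_matrix}")
        if self.suitability_dir is not None and not Path(self.suitability_dir).is_dir():
            raise FileNotFoundError(f"suitability_dir does not exist: {self.suitability_dir}")
        if self.d4_threshold < 0 or self.high_score_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.a_source not in ("sdm", "records"):
            raise ValueError(f"unknown a_source {self.a_source!r}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["extent"] = list(self.extent)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["extent"] = tuple(d["extent"])
        return cls(**d)


@dataclass
class AnalysisResult:
    """Everything one run computes, in memory."""

    grid: GridSpec
    covers: HabitatCoverStack
    cmap: CimpalMap
    sdm_cmap: CimpalMap
    record_cmap: CimpalMap
    weights: ImpactWeightTable
    partition: RegionPartition
    habitat_table: pd.DataFrame
    group_table: pd.DataFrame
    group_maps: dict[str, np.ndarray]
    indicator_table: pd.DataFrame
    high_frequency: pd.DataFrame
    coastal_mask: np.ndarray
    open_sea_mask: np.ndarray


def analyze(
    covers: HabitatCoverStack,
    layers_sdm: dict[str, SpeciesLayer],
    layers_rec: dict[str, SpeciesLayer],
    weights: ImpactWeightTable,
    groups: dict[str, str],
    d4_threshold: float,
    high_score_threshold: float,
    boundary_latitude: float | None,
    records: pd.DataFrame,
    exclude: list[str] | None = None,
    a_source: str = "sdm",
    d2_d4_source: str = "sdm",
    cover_weighted_mean: bool = False,
) -> AnalysisResult:
    """Core analysis shared by the file-based and synthetic drivers."""
    grid = covers.grid
    all_species = sorted(set(layers_sdm) | set(layers_rec))
    for sp in all_species:
        if sp not in groups:
            raise PipelineError("layers", f"species {sp!r} has no biotic group")

    if a_source == "records":
        primary = [layers_rec[sp] for sp in all_species if sp in layers_rec]
    else:
        primary = [
            layers_sdm[sp] if sp in layers_sdm else layers_rec[sp] for sp in all_species
        ]
    cmap = compute_cimpal(primary, covers, weights)
    sdm_cmap = compute_cimpal(list(layers_sdm.values()), covers, weights)
    record_cmap = compute_cimpal(list(layers_rec.values()), covers, weights)

    habitat_table = habitat_disaggregation(
        primary, covers, weights, cover_weighted_mean=cover_weighted_mean
    )
    group_table, group_maps = group_disaggregation(
        cmap, groups, all_groups=sorted(set(groups.values()))
    )

    boundary = (
        boundary_latitude
        if boundary_latitude is not None
        else 0.5 * (grid.lat_min + grid.lat_max)
    )
    partition = partition_regions(grid, covers.study_mask, boundary)
    high_frequency = high_score_frequency(cmap, high_score_threshold, partition)

    indicator_table = build_indicator_table(
        records,
        grid,
        covers.study_mask,
        sdm_maps=sdm_cmap.per_species,
        record_maps=record_cmap.per_species,
        groups=groups,
        d4_threshold=d4_threshold,
        d2_d4_source=d2_d4_source,
    )
    indicator_table = add_ranks(indicator_table, exclude=exclude or [])

    coastal, open_sea = zone_masks(covers)
    return AnalysisResult(
        grid=grid,
        covers=covers,
        cmap=cmap,
        sdm_cmap=sdm_cmap,
        record_cmap=record_cmap,
        weights=weights,
        partition=partition,
        habitat_table=habitat_table,
        group_table=group_table,
        group_maps=group_maps,
        indicator_table=indicator_table,
        high_frequency=high_frequency,
        coastal_mask=coastal,
        open_sea_mask=open_sea,
    )


def export_maps(result: AnalysisResult, output_dir, fmt: str = "geotiff") -> list[Path]:
    """Write the total, per-species, per-group and per-habitat score maps.

    GeoTIFF per map plus one long-format CSV of per-cell total scores.
    """
    if fmt != "geotiff":
        raise ValueError(f"unknown map format {fmt!r}")
    output_dir = Path(output_dir)
    maps_dir = output_dir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, array: np.ndarray) -> None:
        path = maps_dir / f"{name}.tif"
        cio.write_geotiff(array, result.grid, path)
        written.append(path)

    _write("cimpal_total", result.cmap.total)
    for sp, s_map in sorted(result.cmap.per_species.items()):
        _write(f"species_{sp}", s_map)
    for g, g_map in sorted(result.group_maps.items()):
        _write(f"group_{g}", g_map)
    long_df = cio.map_to_long(result.cmap.total, result.covers.study_mask)
    csv_path = output_dir / "cimpal_cells.csv"
    long_df.to_csv(csv_path, index=False, float_format=cio.FLOAT_FORMAT)
    written.append(csv_path)
    return written


def _write_tables(result: AnalysisResult, output_dir: Path) -> list[Path]:
    written = []

    def _csv(name: str, df: pd.DataFrame) -> None:
        path = output_dir / name
        df.to_csv(path, index=False, float_format=cio.FLOAT_FORMAT)
        written.append(path)

    _csv("habitat_disaggregation.csv", result.habitat_table)
    _csv("group_disaggregation.csv", result.group_table)
    _csv("indicators.csv", result.indicator_table)
    _csv("high_score_frequency.csv", result.high_frequency)
    _csv(
        "covers.csv",
        cio.covers_to_long(result.covers.covers, result.covers.study_mask),
    )
    return written


def run_pipeline(config: RunConfig, seed: int | None = None) -> AnalysisResult:
    """Execute the full file-based workflow and write all products.

    Stage failures abort with a stage-named :class:`PipelineError`;
    validation warnings are collected and logged, not fatal.
    """
    t0 = time.perf_counter()
    timings: list[tuple[str, float]] = []
    caught: list[str] = []

    def _stage(name: str):
        timings.append((name, time.perf_counter() - t0))

    config.validate()
    output_dir = Path(config.output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # --- grid & covers
        try:
            grid = build_grid(config.extent, config.resolution)
            polygons, study_area = cio.load_habitat_polygons(config.habitat_geojson)
            covers = rasterize_covers(
                polygons, grid, study_area=study_area, mask_rule=config.mask_rule
            )
            problems = covers.validate()
            if problems:
                raise ValueError("; ".join(problems))
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("rasterize", str(e)) from e
        _stage("rasterize")

        # --- species layers
        try:
            records = cio.load_records(config.records_csv)
            meta = cio.load_species_metadata(config.species_metadata_csv)
            groups = dict(zip(meta["species"], meta["biotic_group"]))
            layers_rec: dict[str, SpeciesLayer] = {}
            layers_sdm: dict[str, SpeciesLayer] = {}
            for sp in meta["species"]:
                layers_rec[sp] = layer_from_records(
                    records, grid, covers.study_mask, sp, biotic_group=groups[sp]
                )
                if config.suitability_dir is not None:
                    tif = Path(config.suitability_dir) / f"{sp}.tif"
                    if tif.exists():
                        raster = cio.read_suitability_raster(tif, grid)
                        layers_sdm[sp] = layer_from_suitability(
                            raster,
                            grid,
                            covers.study_mask,
                            sp,
                            rescale=config.rescale,
                            biotic_group=groups[sp],
                        )
        except Exception as e:
            raise PipelineError("layers", str(e)) from e
        _stage("layers")

        # --- weights
        try:
            entries = cio.load_evidence(config.evidence_csv)
            known_species = set(meta["species"])
            known_habitats = set(default_catalog())
            for e in entries:
                if e.species_id not in known_species:
                    raise ValueError(f"evidence names unknown species {e.species_id!r}")
                if e.habitat_id not in known_habitats:
                    raise ValueError(f"evidence names unknown habitat {e.habitat_id!r}")
            matrix = (
                cio.load_weight_matrix(config.weight_matrix)
                if config.weight_matrix is not None
                else cio.default_weight_matrix()
            )
            weights = resolve_weights(entries, matrix)
        except Exception as e:
            raise PipelineError("weights", str(e)) from e
        _stage("weights")

        # --- scores, disaggregations, indicators
        try:
            result = analyze(
                covers,
                layers_sdm,
                layers_rec,
                weights,
                groups,
                d4_threshold=config.d4_threshold,
                high_score_threshold=config.high_score_threshold,
                boundary_latitude=config.boundary_latitude,
                records=records,
                exclude=config.exclude,
                a_source=config.a_source,
                d2_d4_source=config.d2_d4_source,
                cover_weighted_mean=config.cover_weighted_mean,
            )
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("compute", str(e)) from e
        _stage("compute")

        caught = [str(w.message) for w in wrec]

    # --- outputs
    try:
        export_maps(result, output_dir)
        _write_tables(result, output_dir)
        primary = _primary_layers(layers_sdm, layers_rec, config.a_source)
        for habitat_id in sorted(result.covers.covers):
            hmap = habitat_score_map(primary, result.covers, result.weights, habitat_id)
            cio.write_geotiff(hmap, grid, output_dir / "maps" / f"habitat_{habitat_id}.tif")
        config.to_yaml(output_dir / "run_config.yaml")
        cio.write_manifest(
            output_dir,
            {
                "seed": seed,
                "n_warnings": len(caught),
                "species": sorted(groups),
                "extent": list(config.extent),
                "resolution": config.resolution,
            },
        )
        _stage("write")
        log_lines = [f"{name}: t+{t:.3f}s" for name, t in timings]
        log_lines += [f"warning: {m}" for m in caught]
        (output_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    except Exception as e:
        raise PipelineError("write", str(e)) from e
    return result


def _primary_layers(layers_sdm, layers_rec, a_source):
    all_species = sorted(set(layers_sdm) | set(layers_rec))
    if a_source == "records":
        return [layers_rec[sp] for sp in all_species if sp in layers_rec]
    return [layers_sdm[sp] if sp in layers_sdm else layers_rec[sp] for sp in all_species]


def run_scenario(
    scenario: Scenario,
    matrix: WeightMatrix | None = None,
    exclude: list[str] | None = None,
    a_source: str = "sdm",
) -> AnalysisResult:
    """Run the analysis on an in-memory synthetic scenario."""
    cfg = scenario.config
    covers = scenario.seascape.stack
    groups = dict(zip(scenario.species_meta["species"], scenario.species_meta["biotic_group"]))
    layers_sdm = {
        sp: SpeciesLayer(sp, "sdm", scenario.suitability[sp], biotic_group=groups[sp])
        for sp in scenario.suitability
    }
    layers_rec = {
        sp: layer_from_records(
            scenario.records, covers.grid, covers.study_mask, sp, biotic_group=groups[sp]
        )
        for sp in groups
    }
    if matrix is None:
        matrix = cio.default_weight_matrix()
    weights = resolve_weights(scenario.evidence, matrix)
    return analyze(
        covers,
        layers_sdm,
        layers_rec,
        weights,
        groups,
        d4_threshold=cfg.d4_threshold,
        high_score_threshold=cfg.high_score_threshold,
        boundary_latitude=cfg.boundary_latitude,
        records=scenario.records,
        exclude=exclude,
        a_source=a_source,
    )


# ------------------------------------------------- scenario input export


def covers_to_polygons(stack: HabitatCoverStack) -> list[tuple[str, object]]:
    """Represent a cover stack as habitat polygons that rasterize back
    to the same per-cell fractions.

    Each covered cell contributes a sub-rectangle spanning the cell's
    full width with height scaled by the cover fraction, so degree-space
    rasterization recovers the fraction exactly.
    """
    grid = stack.grid
    res = grid.resolution
    out = []
    for habitat_id in stack.benthic_ids():
        cov = stack.covers[habitat_id]
        r, c = np.nonzero(cov > 0)
        if r.size == 0:
            continue
        x0 = grid.lon_min + c * res
        y1 = grid.lat_max - r * res
        boxes = shapely.box(x0, y1 - cov[r, c] * res, x0 + res, y1)
        out.append((habitat_id, shapely.union_all(boxes)))
    return out


def write_scenario_inputs(scenario: Scenario, input_dir) -> RunConfig:
    """Materialize a synthetic scenario as the pipeline's file formats.

    Writes habitat GeoJSON, records/evidence/metadata CSVs, per-species
    suitability GeoTIFFs and the weight-matrix config, and returns a
    ready :class:`RunConfig` pointing an output directory next to them.
    """
    input_dir = Path(input_dir)
    input_dir.mkdir(parents=True, exist_ok=True)
    grid = scenario.seascape.grid
    study_area = shapely.box(grid.lon_min, grid.lat_min, grid.lon_max, grid.lat_max)
    cio.save_habitat_polygons(
        covers_to_polygons(scenario.seascape.stack),
        input_dir / "habitats.geojson",
        study_area=study_area,
    )
    cio.save_records(scenario.records, input_dir / "records.csv")
    cio.save_evidence(scenario.evidence, input_dir / "evidence.csv")
    scenario.species_meta.to_csv(input_dir / "species_metadata.csv", index=False)
    matrix = cio.default_weight_matrix()
    cio.save_weight_matrix(matrix, input_dir / "weight_matrix.yaml")
    suit_dir = input_dir / "suitability"
    suit_dir.mkdir(exist_ok=True)
    for sp, raster in scenario.suitability.items():
        cio.write_geotiff(raster, grid, suit_dir / f"{sp}.tif")
    cfg = scenario.config
    return RunConfig(
        habitat_geojson=str(input_dir / "habitats.geojson"),
        records_csv=str(input_dir / "records.csv"),
        evidence_csv=str(input_dir / "evidence.csv"),
        species_metadata_csv=str(input_dir / "species_metadata.csv"),
        output_dir=str(input_dir / "output"),
        extent=tuple(cfg.extent),
        resolution=cfg.resolution,
        weight_matrix=str(input_dir / "weight_matrix.yaml"),
        suitability_dir=str(suit_dir),
        d4_threshold=cfg.d4_threshold,
        high_score_threshold=cfg.high_score_threshold,
        boundary_latitude=cfg.boundary_latitude,
    )
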