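"""Readers and writers for the pipeline's standard formats.

GeoJSON carries habitat and study-area polygons, CSV carries tabular
inputs and outputs, and single-band GeoTIFF carries every gridded layer.
GeoTIFFs are written through tifffile with the standard georeferencing
tags (ModelPixelScale, ModelTiepoint, a minimal EPSG:4326 geo-key
directory), north-up with one pixel per grid cell, float32.

All floating-point CSV output uses 9 significant digits so repeated runs
diff cleanly without false precision.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec
from .weights import EvidenceEntry, WeightMatrix

FLOAT_FORMAT = "%.9g"

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
# GeoKeyDirectory: version 1.1.0, 3 keys -> geographic model, area raster, WGS84
_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


# ---------------------------------------------------------------- CSV tables


def load_records(path) -> pd.DataFrame:
    """Occurrence records: CSV with header species,lon,lat[,source]."""
    df = pd.read_csv(path)
    needed = ["species", "lon", "lat"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"records file {path} missing columns {missing}")
    return df


def save_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def load_evidence(path) -> list[EvidenceEntry]:
    """Evidence table: CSV with header species,habitat,magnitude,evidence."""
    df = pd.read_csv(path)
    needed = ["species", "habitat", "magnitude", "evidence"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"evidence file {path} missing columns {missing}")
    return [
        EvidenceEntry(r.species, r.habitat, r.magnitude, r.evidence)
        for r in df.itertuples(index=False)
    ]


def save_evidence(entries: list[EvidenceEntry], path) -> None:
    df = pd.DataFrame(
        [(e.species_id, e.habitat_id, e.magnitude, e.evidence) for e in entries],
        columns=["species", "habitat", "magnitude", "evidence"],
    )
    df.to_csv(path, index=False)


def load_species_metadata(path) -> pd.DataFrame:
    """Species metadata: CSV with header species,biotic_group[,status]."""
    df = pd.read_csv(path)
    needed = ["species", "biotic_group"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"species metadata {path} missing columns {missing}")
    return df


# ------------------------------------------------------------ weight matrix


def load_weight_matrix(path) -> WeightMatrix:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return WeightMatrix.from_config(cfg)


def save_weight_matrix(matrix: WeightMatrix, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(matrix.to_config(), fh, sort_keys=False)


def default_weight_matrix() -> WeightMatrix:
    """The packaged default weighting (EICAT-style magnitude ranks)."""
    ref = importlib.resources.files("cimpal.data") / "default_weights.yaml"
    return WeightMatrix.from_config(yaml.safe_load(ref.read_text()))


# ----------------------------------------------------------------- GeoJSON


def load_habitat_polygons(path) -> tuple[list[tuple[str, BaseGeometry]], BaseGeometry | None]:
    """Read a GeoJSON FeatureCollection of habitat polygons.

    Each feature's ``habitat`` property names its habitat type; a
    feature with ``role: study_area`` (and no habitat) delimits the
    analysis domain. Returns (tagged polygons, study area or None).
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
    polygons: list[tuple[str, BaseGeometry]] = []
    study_area: BaseGeometry | None = None
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if props.get("role") == "study_area":
            study_area = geom if study_area is None else shapely.union(study_area, geom)
        elif "habitat" in props:
            polygons.append((props["habitat"], geom))
        else:
            raise ValueError("feature without 'habitat' property or study_area role")
    return polygons, study_area


def save_habitat_polygons(
    polygons: list[tuple[str, BaseGeometry]],
    path,
    study_area: BaseGeometry | None = None,
) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"habitat": habitat_id},
            "geometry": mapping(geom),
        }
        for habitat_id, geom in polygons
    ]
    if study_area is not None:
        features.append(
            {
                "type": "Feature",
                "properties": {"role": "study_area"},
                "geometry": mapping(study_area),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ----------------------------------------------------------------- GeoTIFF


def write_geotiff(array: np.ndarray, grid: GridSpec, path) -> None:
    """Write one gridded layer as a north-up float32 GeoTIFF."""
    if array.shape != grid.shape:
        raise ValueError(f"array shape {array.shape} != grid shape {grid.shape}")
    res = grid.resolution
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.lon_min, grid.lat_max, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_GEO_KEYS), _GEO_KEYS),
    ]
    tifffile.imwrite(path, array.astype(np.float32), extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, dict]:
    """Read a GeoTIFF written by :func:`write_geotiff`.

    Returns the float array and a georeferencing dict with keys
    ``lon_min``, ``lat_max``, ``res_x``, ``res_y`` (empty when the file
    carries no geo tags).
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        array = page.asarray().astype(float)
        geo: dict = {}
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE in tags and _TAG_MODEL_TIEPOINT in tags:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tie = tags[_TAG_MODEL_TIEPOINT].value
            geo = {
                "res_x": float(scale[0]),
                "res_y": float(scale[1]),
                "lon_min": float(tie[3]),
                "lat_max": float(tie[4]),
            }
    return array, geo


def read_suitability_raster(path, grid: GridSpec, tol: float = 1e-7) -> np.ndarray:
    """Read a per-species suitability GeoTIFF and check grid congruence."""
    array, geo = read_geotiff(path)
    if array.shape != grid.shape:
        raise ValueError(
            f"suitability raster {path}: shape {array.shape} != grid {grid.shape}"
        )
    if geo:
        mism = (
            abs(geo["lon_min"] - grid.lon_min) > tol
            or abs(geo["lat_max"] - grid.lat_max) > tol
            or abs(geo["res_x"] - grid.resolution) > tol
        )
        if mism:
            raise ValueError(f"suitability raster {path} georeferencing mismatch")
    return array


# --------------------------------------------------------------- long table


def covers_to_long(covers: dict[str, np.ndarray], mask: np.ndarray) -> pd.DataFrame:
    """Long-format (row, col, habitat, cover) table over masked cells."""
    rows = []
    mask = np.asarray(mask, dtype=bool)
    for habitat_id in sorted(covers):
        r, c = np.nonzero(mask & (covers[habitat_id] != 0))
        rows.append(
            pd.DataFrame(
                {
                    "row": r,
                    "col": c,
                    "habitat": habitat_id,
                    "cover": covers[habitat_id][r, c],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["row", "col", "habitat", "cover"])
    return pd.concat(rows, ignore_index=True)


def map_to_long(array: np.ndarray, mask: np.ndarray, value_name: str = "score") -> pd.DataFrame:
    """Long-format per-masked-cell table of one gridded layer."""
    mask = np.asarray(mask, dtype=bool)
    r, c = np.nonzero(mask)
    return pd.DataFrame({"row": r, "col": c, value_name: np.asarray(array)[r, c]})


# ----------------------------------------------------------------- manifest


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(output_dir, entries: dict, path_name: str = "manifest.json") -> Path:
    """Machine-readable run manifest listing every output with its hash."""
    output_dir = Path(output_dir)
    # the timing log is intentionally left out so manifests are reproducible
    skip = {path_name, "run.log"}
    files = sorted(
        p for p in output_dir.rglob("*") if p.is_file() and p.name not in skip
    )
    manifest = {
        **entries,
        "outputs": [
            {"path": str(p.relative_to(output_dir)), "sha256": file_sha256(p)}
            for p in files
        ],
    }
    out = output_dir / path_name
    with open(out, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
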