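"""Per-species standardized population-state layers.

The cumulative-impact formula consumes, per species *i*, a per-cell
population state A_i on [0, 1]. Two sources are supported, mirroring
common practice in invasion impact mapping:

* presence records — A_i is binary: 1 in every masked cell holding at
  least one occurrence record, 0 elsewhere;
* habitat-suitability rasters (the output of an upstream species
  distribution model ensemble) — A_i is the continuous suitability,
  optionally min-max rescaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, cells_of

BIOTIC_GROUPS = ("invertebrates", "macrophytes", "fish")

RECORD_COLUMNS = ("species", "lon", "lat")


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check a record table for the required columns and finite coordinates."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table missing columns {missing}")
    if records["species"].isna().any() or (records["species"] == "").any():
        raise ValueError("record table contains empty species ids")
    coords = records[["lon", "lat"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("record table contains non-finite coordinates")
    return records


@dataclass
class SpeciesLayer:
    """Standardized per-cell population state of one species.

    ``method`` records the provenance: 'records' layers are binary,
    'sdm' layers carry continuous suitabilities. ``n_skipped`` counts
    records that fell outside the grid extent (reported, never silently
    dropped).
    """

    species_id: str
    method: str  # 'records' | 'sdm'
    A: np.ndarray
    biotic_group: str | None = None
    n_skipped: int = field(default=0)

    def __post_init__(self):
        if self.method not in ("records", "sdm"):
            raise ValueError(f"unknown layer method {self.method!r}")
        if self.biotic_group is not None and self.biotic_group not in BIOTIC_GROUPS:
            raise ValueError(f"unknown biotic group {self.biotic_group!r}")


def layer_from_records(
    records: pd.DataFrame,
    grid: GridSpec,
    mask: np.ndarray,
    species_id: str,
    biotic_group: str | None = None,
) -> SpeciesLayer:
    """Binary presence layer: 1 in masked cells with >=1 record.

    Duplicate records in one cell count once; records outside the grid
    extent are counted in ``n_skipped``. A species with no rows yields an
    all-zero layer with a warning.
    """
    validate_records(records)
    mask = np.asarray(mask, dtype=bool)
    rows = records.loc[records["species"] == species_id]
    A = np.zeros(grid.shape)
    n_skipped = 0
    if len(rows) == 0:
        warnings.warn(f"no records for species {species_id!r}; empty layer", stacklevel=2)
    else:
        lon = rows["lon"].to_numpy(dtype=float)
        lat = rows["lat"].to_numpy(dtype=float)
        inside = grid.contains(lon, lat)
        n_skipped = int(np.count_nonzero(~inside))
        if inside.any():
            r, c = cells_of(lon[inside], lat[inside], grid)
            A[r, c] = 1.0
        A[~mask] = 0.0
    return SpeciesLayer(
        species_id=species_id,
        method="records",
        A=A,
        biotic_group=biotic_group,
        n_skipped=n_skipped,
    )


def layer_from_suitability(
    raster: np.ndarray,
    grid: GridSpec,
    mask: np.ndarray,
    species_id: str,
    rescale: str = "none",
    biotic_group: str | None = None,
    resample: bool = False,
) -> SpeciesLayer:
    """Continuous population-state layer from a suitability raster.

    ``rescale='none'`` passes values through (they must already lie in
    [0, 1]); ``'minmax'`` maps the observed range onto [0, 1], sending a
    constant raster to all zeros with a warning. A raster whose shape
    differs from the grid is only accepted with ``resample=True``, in
    which case it is nearest-neighbour resampled assuming a shared
    extent.
    """
    if rescale not in ("none", "minmax"):
        raise ValueError(f"unknown rescale mode {rescale!r}")
    raster = np.asarray(raster, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if raster.shape != grid.shape:
        if not resample:
            raise ValueError(
                f"raster shape {raster.shape} != grid shape {grid.shape} "
                "(pass resample=True for nearest-neighbour resampling)"
            )
        src_r = np.minimum(
            (np.arange(grid.n_rows) + 0.5) * raster.shape[0] / grid.n_rows,
            raster.shape[0] - 1,
        ).astype(int)
        src_c = np.minimum(
            (np.arange(grid.n_cols) + 0.5) * raster.shape[1] / grid.n_cols,
            raster.shape[1] - 1,
        ).astype(int)
        raster = raster[np.ix_(src_r, src_c)]
    if not np.all(np.isfinite(raster)):
        raise ValueError("suitability raster contains non-finite values")

    if rescale == "none":
        if raster.min() < 0 or raster.max() > 1:
            raise ValueError(
                "suitability values outside [0, 1] under rescale='none'; "
                "use rescale='minmax' to standardize"
            )
        A = raster.copy()
    else:
        lo, hi = float(raster.min()), float(raster.max())
        if hi - lo == 0:
            warnings.warn(
                f"constant suitability raster for {species_id!r}; "
                "degenerate min-max range maps to all zeros",
                stacklevel=2,
            )
            A = np.zeros_like(raster)
        else:
            A = (raster - lo) / (hi - lo)

    A = A.copy()
    A[~mask] = 0.0
    return SpeciesLayer(
        species_id=species_id, method="sdm", A=A, biotic_group=biotic_group
    )
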