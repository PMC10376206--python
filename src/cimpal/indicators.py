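"""Species-level impact indicators and exclusion-aware rankings.

Four indicators summarise each species' footprint, mirroring standard
invasion impact assessment practice:

* D1 — occupied range: number of grid cells with at least one record;
* D2 — impacted range: number of cells with impact score strictly > 0;
* D3a / D3b — summed impact score over the whole study area, from the
  modelled (suitability-based) and the record-based score maps;
* D4 — mean impact score over the species' range of occurrence, after
  excluding cells scoring below a threshold (default 0.1); undefined
  (NaN) when no cell qualifies.

Rank 1 is the most impactful species. Ties break lexicographically by
species id so rankings are deterministic.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, cells_of
from .species import validate_records

INDICATORS = ("D1", "D2", "D3a", "D3b", "D4")

#: Cells scoring below this are excluded from the D4 mean.
D4_THRESHOLD_DEFAULT = 0.1


def indicator_d1(
    records: pd.DataFrame, grid: GridSpec, mask: np.ndarray, species_id: str
) -> int:
    """Occupied range: distinct masked cells holding >= 1 record."""
    validate_records(records)
    mask = np.asarray(mask, dtype=bool)
    rows = records.loc[records["species"] == species_id]
    if len(rows) == 0:
        return 0
    lon = rows["lon"].to_numpy(dtype=float)
    lat = rows["lat"].to_numpy(dtype=float)
    inside = grid.contains(lon, lat)
    if not inside.any():
        return 0
    r, c = cells_of(lon[inside], lat[inside], grid)
    occupied = np.zeros(grid.shape, dtype=bool)
    occupied[r, c] = True
    return int(np.count_nonzero(occupied & mask))


def indicator_d2(score_map: np.ndarray) -> int:
    """Impacted range: cells with score strictly above zero (no epsilon)."""
    return int(np.count_nonzero(np.asarray(score_map) > 0))


def indicator_d3(score_map: np.ndarray) -> float:
    """Summed impact score across the study area."""
    return float(np.asarray(score_map).sum())


def indicator_d4(
    score_map: np.ndarray, d4_threshold: float = D4_THRESHOLD_DEFAULT
) -> float:
    """Mean score over the species' range of occurrence.

    Cells scoring strictly below the threshold are excluded; a cell
    scoring exactly the threshold is kept. Returns NaN (undefined, not
    zero) when no cell qualifies.
    """
    s = np.asarray(score_map, dtype=float)
    keep = s >= d4_threshold
    if not keep.any():
        return math.nan
    return float(s[keep].mean())


def build_indicator_table(
    records: pd.DataFrame,
    grid: GridSpec,
    mask: np.ndarray,
    sdm_maps: Mapping[str, np.ndarray],
    record_maps: Mapping[str, np.ndarray],
    groups: Mapping[str, str],
    d4_threshold: float = D4_THRESHOLD_DEFAULT,
    d2_d4_source: str = "sdm",
) -> pd.DataFrame:
    """Assemble D1..D4 for every species.

    ``sdm_maps`` / ``record_maps`` hold per-species score maps S_i from
    the modelled and the record-based population states. D2 and D4 are
    computed from the modelled maps by default (``d2_d4_source='sdm'``,
    falling back to the record map for species without a model); pass
    ``'records'`` to switch them to record-based maps throughout.
    """
    if d2_d4_source not in ("sdm", "records"):
        raise ValueError(f"unknown d2_d4_source {d2_d4_source!r}")
    species = sorted(set(sdm_maps) | set(record_maps))
    rows = []
    for sp in species:
        s_sdm = sdm_maps.get(sp)
        s_rec = record_maps.get(sp)
        if d2_d4_source == "sdm":
            s_ref = s_sdm if s_sdm is not None else s_rec
        else:
            s_ref = s_rec if s_rec is not None else s_sdm
        rows.append(
            {
                "species": sp,
                "biotic_group": groups.get(sp, ""),
                "D1": indicator_d1(records, grid, mask, sp),
                "D2": indicator_d2(s_ref),
                "D3a": indicator_d3(s_sdm) if s_sdm is not None else np.nan,
                "D3b": indicator_d3(s_rec) if s_rec is not None else np.nan,
                "D4": indicator_d4(s_ref, d4_threshold),
            }
        )
    return pd.DataFrame(rows, columns=["species", "biotic_group", *INDICATORS])


def rank_species(
    table: pd.DataFrame, indicator: str, exclude: Sequence[str] = ()
) -> pd.DataFrame:
    """Order species by one indicator, most impactful first.

    Excluded species and species with undefined (NaN) values are left
    out of the ranking; ties break lexicographically by species id.
    """
    if indicator not in INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}; expected one of {INDICATORS}")
    sub = table.loc[
        ~table["species"].isin(set(exclude)) & table[indicator].notna(),
        ["species", indicator],
    ].copy()
    sub = sub.sort_values(
        [indicator, "species"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    sub["rank"] = np.arange(1, len(sub) + 1)
    return sub


def add_ranks(
    table: pd.DataFrame, exclude: Sequence[str] = (), indicators: Iterable[str] = INDICATORS
) -> pd.DataFrame:
    """Annotate an indicator table with rank_D1..rank_D4 columns.

    Excluded species keep their values but carry no ranks and are
    flagged in an ``excluded`` column.
    """
    out = table.copy()
    out["excluded"] = out["species"].isin(set(exclude))
    for ind in indicators:
        ranking = rank_species(table, ind, exclude=exclude)
        rank_map = dict(zip(ranking["species"], ranking["rank"]))
        out[f"rank_{ind}"] = out["species"].map(rank_map).astype("Int64")
    return out
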