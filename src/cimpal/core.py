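"""Per-cell cumulative impact scores and their disaggregations.

The cumulative impact score of a grid cell is

    I_c = sum_i sum_j  A_i * H_j * w_ij

where A_i is the standardized population state of species i in the cell,
H_j the fractional cover of habitat type j, and w_ij the impact weight
of species i on habitat j. The score is additive over species, so the
map decomposes exactly into per-species, per-habitat and per-biotic-
group contributions; the disaggregation helpers below report those
shares together with per-habitat mean scores over each habitat's
support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grid import GridSpec, RegionPartition
from .habitats import HabitatCoverStack, HabitatType
from .species import SpeciesLayer
from .weights import ImpactWeightTable

#: Internal consistency tolerance: the total map must equal the sum of
#: per-species maps to this absolute tolerance.
ADDITIVITY_TOL = 1e-9


@dataclass
class CimpalMap:
    """Cumulative impact surface plus its per-species decomposition."""

    grid: GridSpec
    total: np.ndarray
    per_species: dict[str, np.ndarray]
    study_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def species_ids(self) -> list[str]:
        return list(self.per_species)

    def check_additivity(self) -> float:
        """Max absolute gap between total and the species sum."""
        acc = np.zeros(self.grid.shape)
        for s in self.per_species.values():
            acc += s
        return float(np.max(np.abs(acc - self.total))) if self.per_species else float(
            np.max(np.abs(self.total))
        )


def compute_cimpal(
    layers: Iterable[SpeciesLayer],
    covers: HabitatCoverStack,
    weights: ImpactWeightTable,
) -> CimpalMap:
    """Evaluate the cumulative impact formula on every grid cell.

    Per species the habitat sum ``sum_j H_j * w_ij`` is a fixed field, so
    S_i = A_i * sum_j H_j w_ij and the total is the species sum. The
    computation is deterministic and independent of species order.
    """
    grid = covers.grid
    layers = list(layers)
    per_species: dict[str, np.ndarray] = {}
    for layer in layers:
        if layer.A.shape != grid.shape:
            raise ValueError(
                f"layer {layer.species_id!r} shape {layer.A.shape} != grid {grid.shape}"
            )
        if np.any(layer.A < 0):
            raise ValueError(f"negative population state for {layer.species_id!r}")
        if layer.species_id in per_species:
            raise ValueError(f"duplicate species layer {layer.species_id!r}")
        field_sum = np.zeros(grid.shape)
        for habitat_id, cover in covers.covers.items():
            w = weights.get(layer.species_id, habitat_id)
            if w < 0:
                raise ValueError(
                    f"negative weight for ({layer.species_id}, {habitat_id})"
                )
            if w:
                field_sum += cover * w
        per_species[layer.species_id] = layer.A * field_sum

    # accumulate in sorted species order so the result is bitwise
    # independent of the order layers were supplied in
    total = np.zeros(grid.shape)
    for sp in sorted(per_species):
        total += per_species[sp]
    total[~covers.study_mask] = 0.0
    return CimpalMap(
        grid=grid,
        total=total,
        per_species=per_species,
        study_mask=np.asarray(covers.study_mask, dtype=bool),
        meta={
            "species": sorted(per_species),
            "habitats": sorted(covers.covers),
        },
    )


def _share_frame(rows: list[dict], total: float, columns: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=columns)
    if total > 0:
        df["percent"] = 100.0 * df["sum"] / total
    else:
        # undefined shares, not 0/0
        df["percent"] = np.nan
    return df


def habitat_disaggregation(
    layers: Iterable[SpeciesLayer],
    covers: HabitatCoverStack,
    weights: ImpactWeightTable,
    cover_weighted_mean: bool = False,
) -> pd.DataFrame:
    """Split the grand-total score by habitat type.

    For habitat j the summed score is ``sum_cells sum_i A_i H_j w_ij``
    and the percent share is relative to the grand total. The per-habitat
    mean divides the summed habitat score by the number of masked cells
    where the habitat occurs (H_j > 0); with ``cover_weighted_mean`` it
    divides by the summed cover instead, weighting cells by how much of
    the habitat they hold.
    """
    layers = list(layers)
    mask = np.asarray(covers.study_mask, dtype=bool)
    rows = []
    grand_total = 0.0
    for habitat_id, cover in covers.covers.items():
        score_j = np.zeros(covers.grid.shape)
        for layer in layers:
            w = weights.get(layer.species_id, habitat_id)
            if w:
                score_j += layer.A * cover * w
        score_j[~mask] = 0.0
        support = mask & (cover > 0)
        n_cells = int(np.count_nonzero(support))
        total_j = float(score_j.sum())
        grand_total += total_j
        if cover_weighted_mean:
            denom = float(cover[mask].sum())
        else:
            denom = float(n_cells)
        rows.append(
            {
                "habitat": habitat_id,
                "sum": total_j,
                "mean": total_j / denom if denom > 0 else np.nan,
                "n_cells": n_cells,
            }
        )
    df = _share_frame(rows, grand_total, ["habitat", "sum", "mean", "n_cells"])
    return df[["habitat", "sum", "percent", "mean", "n_cells"]]


def habitat_score_map(
    layers: Iterable[SpeciesLayer],
    covers: HabitatCoverStack,
    weights: ImpactWeightTable,
    habitat_id: str,
) -> np.ndarray:
    """Per-cell score attributable to one habitat type."""
    cover = covers.covers[habitat_id]
    out = np.zeros(covers.grid.shape)
    for layer in layers:
        w = weights.get(layer.species_id, habitat_id)
        if w:
            out += layer.A * cover * w
    out[~np.asarray(covers.study_mask, dtype=bool)] = 0.0
    return out


def group_disaggregation(
    cmap: CimpalMap,
    groups: Mapping[str, str],
    all_groups: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Split the total score by biotic group.

    Every species in the map must be assigned exactly one group; a group
    with no species still appears in the output with zero share. Returns
    the share table and the per-group score maps.
    """
    group_names = list(all_groups) if all_groups is not None else sorted(set(groups.values()))
    maps: dict[str, np.ndarray] = {g: np.zeros(cmap.grid.shape) for g in group_names}
    for species_id, s_map in cmap.per_species.items():
        try:
            g = groups[species_id]
        except KeyError:
            raise KeyError(f"species {species_id!r} has no biotic group") from None
        if g not in maps:
            maps[g] = np.zeros(cmap.grid.shape)
            group_names.append(g)
        maps[g] += s_map
    rows = [{"group": g, "sum": float(maps[g].sum())} for g in group_names]
    grand_total = sum(r["sum"] for r in rows)
    df = _share_frame(rows, grand_total, ["group", "sum"])
    return df[["group", "sum", "percent"]], maps


def high_score_frequency(
    cmap: CimpalMap, threshold: float, partition: RegionPartition
) -> pd.DataFrame:
    """Regional frequency of cells scoring strictly above ``threshold``.

    Returns per-region counts of masked high-score cells and each
    region's fraction of the total high-score count (NaN when no cell
    exceeds the threshold).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = cmap.study_mask & np.asarray(partition.mask, dtype=bool)
    high = mask & (cmap.total > threshold)
    n_south = int(np.count_nonzero(high & partition.south))
    n_north = int(np.count_nonzero(high)) - n_south
    n_total = n_north + n_south
    frac_n = n_north / n_total if n_total else np.nan
    frac_s = n_south / n_total if n_total else np.nan
    return pd.DataFrame(
        {
            "region": ["north", "south"],
            "n_high": [n_north, n_south],
            "fraction": [frac_n, frac_s],
        }
    )


def zone_masks(
    covers: HabitatCoverStack, catalog: Mapping[str, HabitatType] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Coastal and open-sea per-cell masks.

    A cell is coastal when any coastal-zone *benthic* habitat has
    positive cover there; every other masked cell is open sea. The
    pelagic habitat belongs to both zones and never affects the split.
    """
    catalog = catalog if catalog is not None else covers.catalog
    mask = np.asarray(covers.study_mask, dtype=bool)
    coastal = np.zeros(covers.grid.shape, dtype=bool)
    for habitat_id, cover in covers.covers.items():
        ht = catalog[habitat_id]
        if ht.is_pelagic:
            continue
        if ht.zone == "coastal":
            coastal |= cover > 0
    coastal &= mask
    open_sea = mask & ~coastal
    return coastal, open_sea
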