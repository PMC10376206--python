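"""Species impact indicators D1-D4 and exclusion-aware rankings."""

import math

import numpy as np
import pandas as pd
import pytest

from cimpal.core import compute_cimpal
from cimpal.indicators import (
    add_ranks,
    build_indicator_table,
    indicator_d1,
    indicator_d2,
    indicator_d3,
    indicator_d4,
    rank_species,
)
from cimpal.species import layer_from_records

from conftest import HAND_EXPECTED, HAND_GROUPS, HAND_RECORDS


class TestD1:
    def test_records_collapse_to_cells(self, hand_fixture):
        grid, covers, _, _ = hand_fixture
        assert indicator_d1(HAND_RECORDS, grid, covers.study_mask, "sp1") == 3
        assert indicator_d1(HAND_RECORDS, grid, covers.study_mask, "sp2") == 2

    def test_no_records_zero(self, hand_fixture):
        grid, covers, _, _ = hand_fixture
        assert indicator_d1(HAND_RECORDS, grid, covers.study_mask, "ghost") == 0

    def test_many_records_one_cell(self, grid10):
        mask = np.ones(grid10.shape, dtype=bool)
        recs = pd.DataFrame(
            {
                "species": ["sp"] * 1000,
                "lon": np.full(1000, 25.005),
                "lat": np.full(1000, 38.095),
            }
        )
        assert indicator_d1(recs, grid10, mask, "sp") == 1


class TestD2D3D4:
    def test_d2_strict_positivity(self):
        assert indicator_d2(np.array([0.0, 0.0, 0.2, 5.0])) == 2
        assert indicator_d2(np.zeros(4)) == 0
        assert indicator_d2(np.array([1e-15, 0.0])) == 1  # strict, no epsilon

    def test_d3_is_plain_sum(self):
        assert indicator_d3(np.array([0.0, 0.2, 5.0])) == pytest.approx(5.2)
        assert indicator_d3(np.zeros(3)) == 0.0

    def test_d4_exclusion_rule(self):
        assert indicator_d4(np.array([0.05, 0.5, 1.5])) == pytest.approx(1.0)

    def test_d4_boundary_cell_kept(self):
        # "lower than 0.1" excludes only strictly smaller scores
        assert indicator_d4(np.array([0.1])) == pytest.approx(0.1)

    def test_d4_undefined_when_nothing_qualifies(self):
        assert math.isnan(indicator_d4(np.array([0.01, 0.05])))

    def test_d4_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        s = rng.random(100) * 3
        prev = -np.inf
        for thr in (0.0, 0.1, 0.5, 1.0, 2.0):
            v = indicator_d4(s, thr)
            if not math.isnan(v):
                assert v >= prev
                prev = v


class TestIndicatorTable:
    def test_hand_fixture_values(self, hand_fixture):
        grid, covers, layers, weights = hand_fixture
        sdm_cmap = compute_cimpal(layers, covers, weights)
        rec_layers = [
            layer_from_records(HAND_RECORDS, grid, covers.study_mask, sp)
            for sp in ("sp1", "sp2")
        ]
        rec_cmap = compute_cimpal(rec_layers, covers, weights)
        table = build_indicator_table(
            HAND_RECORDS,
            grid,
            covers.study_mask,
            sdm_maps=sdm_cmap.per_species,
            record_maps=rec_cmap.per_species,
            groups=HAND_GROUPS,
        ).set_index("species")
        for sp in ("sp1", "sp2"):
            assert table.loc[sp, "D1"] == HAND_EXPECTED["D1"][sp]
            assert table.loc[sp, "D2"] == HAND_EXPECTED["D2"][sp]
            assert table.loc[sp, "D3a"] == pytest.approx(HAND_EXPECTED["D3a"][sp], abs=1e-12)
            assert table.loc[sp, "D3b"] == pytest.approx(HAND_EXPECTED["D3b"][sp], abs=1e-12)
        assert table.loc["sp1", "D4"] == pytest.approx(HAND_EXPECTED["D4"]["sp1"], abs=1e-12)
        assert math.isnan(table.loc["sp2", "D4"])

    def test_d3b_uniform_field_closed_form(self, grid10):
        # on a uniform weighted-cover field k, D3b = k * D1 exactly
        from cimpal.habitats import HabitatCoverStack, default_catalog
        from cimpal.weights import ImpactWeightTable

        mask = np.ones(grid10.shape, dtype=bool)
        covers = HabitatCoverStack(
            grid10,
            {"pelagic": np.ones(grid10.shape)},
            mask,
            default_catalog(),
        )
        weights = ImpactWeightTable({("sp", "pelagic"): 2.5})
        rng = np.random.default_rng(9)
        recs = pd.DataFrame(
            {
                "species": "sp",
                "lon": rng.uniform(25, 25.1, 40),
                "lat": rng.uniform(38, 38.1, 40),
            }
        )
        layer = layer_from_records(recs, grid10, mask, "sp")
        cmap = compute_cimpal([layer], covers, weights)
        d1 = indicator_d1(recs, grid10, mask, "sp")
        assert indicator_d3(cmap.per_species["sp"]) == pytest.approx(2.5 * d1)


class TestRanking:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame(
            {
                "species": ["X", "Y", "Z"],
                "biotic_group": ["fish"] * 3,
                "D1": [10, 5, 7],
                "D2": [1, 1, 1],
                "D3a": [10.0, 10.0, 1.0],
                "D3b": [0.0, 1.0, 2.0],
                "D4": [np.nan, 2.0, 1.0],
            }
        )

    def test_descending_order(self, table):
        r = rank_species(table, "D1")
        assert r["species"].tolist() == ["X", "Z", "Y"]
        assert r["rank"].tolist() == [1, 2, 3]

    def test_lexicographic_tie_break(self, table):
        r = rank_species(table, "D3a")
        assert r["species"].tolist() == ["X", "Y", "Z"]

    def test_exclusion_removes_from_ranks(self, table):
        r = rank_species(table, "D1", exclude=["X"])
        assert r["species"].tolist() == ["Z", "Y"]
        assert r["rank"].tolist() == [1, 2]

    def test_undefined_values_unranked(self, table):
        r = rank_species(table, "D4")
        assert "X" not in r["species"].tolist()

    def test_unknown_indicator_rejected(self, table):
        with pytest.raises(ValueError, match="unknown indicator"):
            rank_species(table, "D9")

    def test_add_ranks_keeps_excluded_values(self, table):
        out = add_ranks(table, exclude=["X"]).set_index("species")
        assert bool(out.loc["X", "excluded"])
        assert pd.isna(out.loc["X", "rank_D1"])
        assert out.loc["X", "D1"] == 10
        assert out.loc["Z", "rank_D1"] == 1
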