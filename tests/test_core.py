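"""Cumulative score computation and its disaggregations."""

import numpy as np
import pandas as pd
import pytest

from cimpal.core import (
    compute_cimpal,
    group_disaggregation,
    habitat_disaggregation,
    high_score_frequency,
    zone_masks,
)
from cimpal.grid import build_grid, partition_regions
from cimpal.habitats import HabitatCoverStack, default_catalog
from cimpal.species import SpeciesLayer
from cimpal.weights import ImpactWeightTable

from conftest import instance_stack, naive_cimpal, random_instance


def _single_cell_setup(A=1.0, H=1.0, w=3.0):
    grid = build_grid((0, 0, 0.01, 0.01), 0.01)
    mask = np.ones((1, 1), dtype=bool)
    stack = instance_stack((1, 1), {"hab": np.full((1, 1), H)}, grid)
    layer = SpeciesLayer("sp", "sdm", np.full((1, 1), A))
    weights = ImpactWeightTable({("sp", "hab"): w})
    return [layer], stack, weights


class TestComputeCimpal:
    def test_single_term_identity(self):
        layers, stack, weights = _single_cell_setup(A=1, H=1, w=3)
        cmap = compute_cimpal(layers, stack, weights)
        assert cmap.total[0, 0] == pytest.approx(3.0)

    def test_two_species_shared_habitat(self):
        grid = build_grid((0, 0, 0.01, 0.01), 0.01)
        stack = instance_stack((1, 1), {"hab": np.full((1, 1), 0.8)}, grid)
        layers = [
            SpeciesLayer("a", "sdm", np.full((1, 1), 1.0)),
            SpeciesLayer("b", "sdm", np.full((1, 1), 0.5)),
        ]
        weights = ImpactWeightTable({("a", "hab"): 2.0, ("b", "hab"): 4.0})
        cmap = compute_cimpal(layers, stack, weights)
        assert cmap.total[0, 0] == pytest.approx(1 * 0.8 * 2 + 0.5 * 0.8 * 4)

    def test_zero_weights_zero_map(self):
        layers, stack, _ = _single_cell_setup()
        cmap = compute_cimpal(layers, stack, ImpactWeightTable({}))
        assert cmap.total.sum() == 0

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            shape, A, H, w = random_instance(rng)
            stack = instance_stack(shape, H)
            layers = [SpeciesLayer(sp, "sdm", a) for sp, a in A.items()]
            cmap = compute_cimpal(layers, stack, ImpactWeightTable(w))
            total, per_species = naive_cimpal(A, H, w, shape)
            np.testing.assert_allclose(cmap.total, total, atol=1e-12)
            for sp in A:
                np.testing.assert_allclose(cmap.per_species[sp], per_species[sp], atol=1e-12)

    def test_order_independence_and_additivity(self):
        rng = np.random.default_rng(12)
        shape, A, H, w = random_instance(rng)
        stack = instance_stack(shape, H)
        layers = [SpeciesLayer(sp, "sdm", a) for sp, a in A.items()]
        fwd = compute_cimpal(layers, stack, ImpactWeightTable(w))
        rev = compute_cimpal(layers[::-1], stack, ImpactWeightTable(w))
        np.testing.assert_array_equal(fwd.total, rev.total)
        assert fwd.check_additivity() < 1e-9

    def test_monotone_in_population_state(self):
        rng = np.random.default_rng(13)
        shape, A, H, w = random_instance(rng)
        stack = instance_stack(shape, H)
        layers = [SpeciesLayer(sp, "sdm", a) for sp, a in A.items()]
        base = compute_cimpal(layers, stack, ImpactWeightTable(w)).total
        sp0 = list(A)[0]
        bumped = [
            SpeciesLayer(sp, "sdm", np.minimum(a + 0.1, 1.0) if sp == sp0 else a)
            for sp, a in A.items()
        ]
        up = compute_cimpal(bumped, stack, ImpactWeightTable(w)).total
        assert np.all(up >= base - 1e-12)

    def test_grid_mismatch_rejected(self, hand_fixture):
        _, covers, layers, weights = hand_fixture
        bad = SpeciesLayer("bad", "sdm", np.zeros((3, 3)))
        with pytest.raises(ValueError, match="shape"):
            compute_cimpal([bad], covers, weights)

    def test_negative_state_rejected(self):
        layers, stack, weights = _single_cell_setup()
        layers[0].A[:] = -0.5
        with pytest.raises(ValueError, match="negative"):
            compute_cimpal(layers, stack, weights)


class TestHabitatDisaggregation:
    def test_hand_fixture_shares_and_means(self, hand_fixture):
        from conftest import HAND_EXPECTED

        _, covers, layers, weights = hand_fixture
        table = habitat_disaggregation(layers, covers, weights).set_index("habitat")
        assert table.loc["shallow_hard", "percent"] == pytest.approx(
            HAND_EXPECTED["share_hard"], abs=1e-9
        )
        assert table.loc["pelagic", "percent"] == pytest.approx(
            HAND_EXPECTED["share_pelagic"], abs=1e-9
        )
        assert table.loc["shallow_hard", "mean"] == pytest.approx(
            HAND_EXPECTED["mean_hard"], abs=1e-12
        )
        assert table.loc["pelagic", "mean"] == pytest.approx(
            HAND_EXPECTED["mean_pelagic"], abs=1e-12
        )
        assert table["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_habitat_is_total(self):
        layers, stack, weights = _single_cell_setup()
        table = habitat_disaggregation(layers, stack, weights)
        assert table["percent"].iloc[0] == pytest.approx(100.0)

    def test_zero_total_shares_undefined(self):
        layers, stack, _ = _single_cell_setup()
        table = habitat_disaggregation(layers, stack, ImpactWeightTable({}))
        assert table["percent"].isna().all()

    def test_cover_weighted_mean_variant(self, hand_fixture):
        _, covers, layers, weights = hand_fixture
        table = habitat_disaggregation(
            layers, covers, weights, cover_weighted_mean=True
        ).set_index("habitat")
        # summed hard cover = 1 + .5 + .25 + .8 + 1 + .1 = 3.65
        assert table.loc["shallow_hard", "mean"] == pytest.approx(5.51 / 3.65)


class TestGroupDisaggregation:
    def test_hand_fixture_group_shares(self, hand_cmap):
        from conftest import HAND_EXPECTED, HAND_GROUPS

        table, maps = group_disaggregation(
            hand_cmap, HAND_GROUPS, all_groups=["fish", "invertebrates", "macrophytes"]
        )
        t = table.set_index("group")
        assert t.loc["fish", "percent"] == pytest.approx(
            HAND_EXPECTED["share_hard"], abs=1e-9
        )
        assert t.loc["macrophytes", "sum"] == 0.0
        assert "macrophytes" in maps
        assert table["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_species_without_group_rejected(self, hand_cmap):
        with pytest.raises(KeyError, match="sp2"):
            group_disaggregation(hand_cmap, {"sp1": "fish"})

    def test_group_maps_sum_to_total(self, hand_cmap):
        from conftest import HAND_GROUPS

        _, maps = group_disaggregation(hand_cmap, HAND_GROUPS)
        acc = sum(maps.values())
        np.testing.assert_allclose(acc, hand_cmap.total, atol=1e-12)


class TestHighScoreFrequency:
    def test_hand_fixture_split(self, hand_cmap):
        part = partition_regions(hand_cmap.grid, hand_cmap.study_mask, 0.01)
        freq = high_score_frequency(hand_cmap, 1.0, part).set_index("region")
        # cells above 1: (0,0)=2.05 in the north, (1,2)=2.0 in the south
        assert freq.loc["north", "n_high"] == 1
        assert freq.loc["south", "n_high"] == 1
        assert freq.loc["south", "fraction"] == pytest.approx(0.5)

    def test_no_high_cells_fraction_undefined(self, hand_cmap):
        part = partition_regions(hand_cmap.grid, hand_cmap.study_mask, 0.01)
        freq = high_score_frequency(hand_cmap, 1e9, part)
        assert (freq["n_high"] == 0).all()
        assert freq["fraction"].isna().all()

    def test_threshold_below_min_counts_all_masked(self, hand_cmap):
        part = partition_regions(hand_cmap.grid, hand_cmap.study_mask, 0.01)
        freq = high_score_frequency(hand_cmap, -1.0, part)
        assert freq["n_high"].sum() == hand_cmap.study_mask.sum()
        # each region's fraction equals its share of masked cells (5/10 each)
        assert freq["fraction"].tolist() == pytest.approx([0.5, 0.5])


class TestZoneMasks:
    def test_rules(self):
        grid = build_grid((0, 0, 0.03, 0.01), 0.01)
        mask = np.ones((1, 3), dtype=bool)
        covers = {
            "shallow_hard": np.array([[0.2, 0.0, 0.0]]),
            "dysphotic_soft": np.array([[0.0, 0.5, 0.0]]),
            "pelagic": np.ones((1, 3)),
        }
        stack = HabitatCoverStack(grid, covers, mask, default_catalog())
        coastal, open_sea = zone_masks(stack)
        # cell 0 has shallow benthic cover -> coastal; cell 1 only dysphotic,
        # cell 2 only pelagic -> both open sea
        assert coastal.tolist() == [[True, False, False]]
        assert open_sea.tolist() == [[False, True, True]]
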