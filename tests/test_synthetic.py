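"""Synthetic seascape generator: determinism, structure, planted truth."""

import numpy as np
import pytest

from cimpal.habitats import PELAGIC_ID
from cimpal.synthetic import (
    ScenarioConfig,
    band_range,
    build_scenario,
    disc_range,
    gen_records,
    gen_seascape,
    gen_suitability,
    preset,
)


class TestSeascape:
    def test_deterministic_given_seed(self):
        a = gen_seascape(ScenarioConfig(seed=42))
        b = gen_seascape(ScenarioConfig(seed=42))
        for h in a.stack.covers:
            np.testing.assert_array_equal(a.stack.covers[h], b.stack.covers[h])
        np.testing.assert_array_equal(a.depth, b.depth)

    def test_stack_invariants_hold(self):
        sea = gen_seascape(ScenarioConfig(seed=7))
        assert sea.stack.validate() == []

    def test_target_fraction_realized(self):
        cfg = ScenarioConfig(
            seed=1,
            extent=(25.0, 36.0, 26.0, 37.0),  # 100 x 100 cells
            habitat_targets={"shallow_hard": 0.1},
        )
        sea = gen_seascape(cfg)
        frac = np.count_nonzero(sea.stack.covers["shallow_hard"]) / sea.mask.sum()
        assert frac == pytest.approx(0.1, abs=0.02)

    def test_zero_targets_pelagic_only(self):
        cfg = ScenarioConfig(seed=2, habitat_targets={})
        sea = gen_seascape(cfg)
        assert sea.stack.benthic_sum().sum() == 0
        assert (sea.stack.covers[PELAGIC_ID][sea.mask] == 1).all()

    def test_infeasible_targets_rejected(self):
        cfg = ScenarioConfig(habitat_targets={"shallow_hard": 0.7, "shallow_soft": 0.5})
        with pytest.raises(ValueError, match="sum"):
            cfg.validate()

    def test_depth_classes_partition_seabed(self):
        sea = gen_seascape(ScenarioConfig(seed=3))
        assert np.all(sea.depth > 0)


class TestRecords:
    def test_zero_intensity_zero_records(self):
        cfg = ScenarioConfig(seed=0, record_intensity=0.0)
        sea = gen_seascape(cfg)
        recs = gen_records(cfg, sea, {"sp": sea.mask})
        assert len(recs) == 0

    def test_empty_range_warns(self):
        cfg = ScenarioConfig(seed=0)
        sea = gen_seascape(cfg)
        with pytest.warns(UserWarning, match="empty planted range"):
            recs = gen_records(cfg, sea, {"sp": np.zeros(sea.grid.shape, bool)})
        assert len(recs) == 0

    def test_poisson_mean_single_cell(self):
        # one-cell range, intensity 3: Monte-Carlo mean over 1000 seeds ~ 3
        sea = gen_seascape(ScenarioConfig(seed=0))
        rng_range = np.zeros(sea.grid.shape, dtype=bool)
        rng_range[10, 10] = True
        counts = []
        for seed in range(1000):
            cfg = ScenarioConfig(seed=seed, record_intensity=3.0)
            recs = gen_records(cfg, sea, {"sp": rng_range})
            counts.append(len(recs))
        assert np.mean(counts) == pytest.approx(3.0, abs=0.2)

    def test_south_bias_ratio(self):
        # bias 4 over a two-region range: southern counts ~ 4x northern
        sea = gen_seascape(ScenarioConfig(seed=0))
        n_s = n_n = 0
        for seed in range(40):
            cfg = ScenarioConfig(seed=seed, record_intensity=0.5, south_bias=4.0)
            recs = gen_records(cfg, sea, {"sp": sea.mask})
            south = recs["lat"] < sea.partition.boundary_latitude
            n_s += south.sum()
            n_n += (~south).sum()
        assert n_s / n_n == pytest.approx(4.0, rel=0.1)

    def test_records_land_inside_their_range(self):
        cfg = ScenarioConfig(seed=5, record_intensity=1.0)
        sea = gen_seascape(cfg)
        rng_mask = disc_range(sea.grid, (25.25, 36.25), 0.1)
        recs = gen_records(cfg, sea, {"sp": rng_mask})
        from cimpal.grid import cells_of

        r, c = cells_of(recs["lon"].to_numpy(), recs["lat"].to_numpy(), sea.grid)
        assert rng_mask[r, c].all()


class TestSuitability:
    def test_peak_at_center_no_bias(self):
        cfg = ScenarioConfig(seed=0, south_bias=1.0)
        sea = gen_seascape(cfg)
        center = (25.255, 36.255)
        s = gen_suitability(cfg, sea, center)
        from cimpal.grid import cell_of

        r, c = cell_of(*center, sea.grid)
        assert s[r, c] == pytest.approx(1.0, abs=1e-6)
        assert s.max() <= 1.0 and s.min() >= 0.0

    def test_decays_with_distance(self):
        cfg = ScenarioConfig(seed=0, south_bias=1.0)
        sea = gen_seascape(cfg)
        s = gen_suitability(cfg, sea, (25.25, 36.25), radius=0.05)
        assert s[0, 0] < 1e-6  # far corner ~ the kernel tail

    def test_halving_radius_shrinks_high_suitability_area(self):
        cfg = ScenarioConfig(seed=0, south_bias=1.0)
        sea = gen_seascape(cfg)
        wide = gen_suitability(cfg, sea, (25.25, 36.25), radius=0.1)
        narrow = gen_suitability(cfg, sea, (25.25, 36.25), radius=0.05)
        n_wide = np.count_nonzero(wide > 0.5)
        n_narrow = np.count_nonzero(narrow > 0.5)
        # area above a level set scales with radius^2 -> a factor ~4
        assert n_narrow == pytest.approx(n_wide / 4, rel=0.1)

    def test_south_ramp_boosts_south(self):
        cfg = ScenarioConfig(seed=0, south_bias=4.0)
        sea = gen_seascape(cfg)
        s = gen_suitability(cfg, sea, (25.25, 36.25), radius=0.08)
        r_mid = sea.grid.n_rows // 2
        col = sea.grid.n_cols // 2
        assert s[r_mid + 10, col] > s[r_mid - 10, col]


class TestScenario:
    def test_same_seed_identical_scenarios(self):
        a = build_scenario(preset("south_hotspot", seed=9))
        b = build_scenario(preset("south_hotspot", seed=9))
        assert a.records.equals(b.records)
        assert a.evidence == b.evidence
        assert a.ground_truth_ordering == b.ground_truth_ordering
        for sp in a.suitability:
            np.testing.assert_array_equal(a.suitability[sp], b.suitability[sp])

    def test_worst_species_leads_ground_truth(self):
        sc = build_scenario(preset("south_hotspot", seed=4))
        assert sc.ground_truth_ordering[0] == sc.worst_species
        top = sc.config.magnitude_pool[-1]
        worst_entries = [e for e in sc.evidence if e.species_id == sc.worst_species]
        assert worst_entries and all(e.magnitude == top for e in worst_entries)
        others = [e for e in sc.evidence if e.species_id != sc.worst_species]
        assert all(e.magnitude != top for e in others)

    def test_empty_preset_has_no_species(self):
        sc = build_scenario(preset("empty", seed=0))
        assert len(sc.species_meta) == 0
        assert len(sc.records) == 0
        assert sc.evidence == []

    def test_records_roundtrip_through_csv(self, tmp_path):
        from cimpal.io import load_records, save_records

        sc = build_scenario(preset("uniform", seed=6))
        path = tmp_path / "records.csv"
        save_records(sc.records, path)
        back = load_records(path)
        assert len(back) == len(sc.records)
        assert (back["species"] == sc.records["species"].to_numpy()).all()
        np.testing.assert_allclose(back["lon"], sc.records["lon"], rtol=1e-8)

    def test_band_range_is_latitude_band(self):
        sea = gen_seascape(ScenarioConfig(seed=0))
        band = band_range(sea.grid, 36.2, 36.3)
        lats = sea.grid.row_lats()
        rows = np.nonzero(band[:, 0])[0]
        assert ((lats[rows] >= 36.2) & (lats[rows] < 36.3)).all()
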