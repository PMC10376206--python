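"""Shared fixtures: a tiny hand-computable study and a naive oracle.

The hand fixture is a 10-cell (2 x 5) grid with two habitats (shallow
hard substrate + pelagic) and two species, small enough that every
downstream quantity — per-cell scores, habitat shares, D1..D4 — is
worked out by hand in HAND_EXPECTED and asserted exactly.
"""

import numpy as np
import pandas as pd
import pytest

from cimpal.core import compute_cimpal
from cimpal.grid import build_grid
from cimpal.habitats import HabitatCoverStack, default_catalog
from cimpal.species import SpeciesLayer
from cimpal.weights import ImpactWeightTable
from cimpal.io import default_weight_matrix


def naive_cimpal(A_by_species, H_by_habitat, w, shape):
    """Plain triple-nested-loop reference for the cumulative score.

    Deliberately written cell-by-cell, species-by-species,
    habitat-by-habitat so it shares nothing with the array
    implementation.
    """
    total = np.zeros(shape)
    per_species = {sp: np.zeros(shape) for sp in A_by_species}
    for r in range(shape[0]):
        for c in range(shape[1]):
            for sp, A in A_by_species.items():
                s = 0.0
                for hab, H in H_by_habitat.items():
                    s += A[r, c] * H[r, c] * w.get((sp, hab), 0.0)
                per_species[sp][r, c] = s
                total[r, c] += s
    return total, per_species


@pytest.fixture(scope="session")
def rank_matrix():
    """Default weight matrix: weight = 1-based magnitude rank."""
    return default_weight_matrix()


@pytest.fixture()
def grid10():
    """10 x 10 grid at 0.01 degrees starting at (25.0, 38.0)."""
    return build_grid((25.0, 38.0, 25.1, 38.1), 0.01)


# ------------------------------------------------------- the hand fixture

HAND_A1 = np.array(
    [
        [1.0, 0.5, 0.2, 0.1, 0.0],
        [0.6, 0.0, 1.0, 0.0, 0.0],
    ]
)
HAND_A2 = np.array(
    [
        [0.05, 0.05, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0],
    ]
)
HAND_H_HARD = np.array(
    [
        [1.0, 0.5, 0.0, 0.25, 0.0],
        [0.8, 0.0, 1.0, 0.0, 0.1],
    ]
)

# sp1 impacts shallow hard substrate with weight 2, sp2 the pelagic
# habitat with weight 1; S1 = 2 * A1 * H_hard, S2 = A2 (pelagic cover 1)
HAND_S1 = np.array(
    [
        [2.0, 0.5, 0.0, 0.05, 0.0],
        [0.96, 0.0, 2.0, 0.0, 0.0],
    ]
)
HAND_S2 = HAND_A2.copy()

HAND_EXPECTED = {
    "total_sum": 5.61,
    "s1_sum": 5.51,
    "s2_sum": 0.1,
    "share_hard": 100.0 * 5.51 / 5.61,
    "share_pelagic": 100.0 * 0.1 / 5.61,
    # 6 cells carry hard-substrate cover; pelagic covers all 10
    "mean_hard": 5.51 / 6.0,
    "mean_pelagic": 0.1 / 10.0,
    "D1": {"sp1": 3, "sp2": 2},
    "D2": {"sp1": 5, "sp2": 2},
    "D3a": {"sp1": 5.51, "sp2": 0.1},
    # record-based scores: sp1 cells (0,0),(0,1),(1,0) -> 2 + 1 + 1.6;
    # sp2 cells (0,0),(0,4) -> 1 + 1
    "D3b": {"sp1": 4.6, "sp2": 2.0},
    # sp1: cell (0,3) scores 0.05 < 0.1 and is excluded -> mean(2, .5, .96, 2)
    "D4": {"sp1": 5.46 / 4.0, "sp2": float("nan")},
}

HAND_RECORDS = pd.DataFrame(
    {
        "species": ["sp1"] * 5 + ["sp2"] * 2,
        "lon": [0.005, 0.002, 0.015, 0.005, 0.008, 0.005, 0.045],
        "lat": [0.015, 0.018, 0.015, 0.005, 0.002, 0.012, 0.015],
    }
)

HAND_GROUPS = {"sp1": "fish", "sp2": "invertebrates"}


@pytest.fixture()
def hand_fixture():
    """The documented 10-cell, 2-species, 2-habitat study."""
    grid = build_grid((0.0, 0.0, 0.05, 0.02), 0.01)
    mask = np.ones(grid.shape, dtype=bool)
    pelagic = np.ones(grid.shape)
    covers = HabitatCoverStack(
        grid=grid,
        covers={"shallow_hard": HAND_H_HARD.copy(), "pelagic": pelagic},
        study_mask=mask,
        catalog=default_catalog(),
    )
    layers = [
        SpeciesLayer("sp1", "sdm", HAND_A1.copy(), biotic_group="fish"),
        SpeciesLayer("sp2", "sdm", HAND_A2.copy(), biotic_group="invertebrates"),
    ]
    weights = ImpactWeightTable({("sp1", "shallow_hard"): 2.0, ("sp2", "pelagic"): 1.0})
    return grid, covers, layers, weights


@pytest.fixture()
def hand_cmap(hand_fixture):
    grid, covers, layers, weights = hand_fixture
    return compute_cimpal(layers, covers, weights)


def random_instance(rng, max_species=5, max_habitats=4, max_cells=200):
    """A random small instance for oracle-equivalence checks."""
    n_rows = int(rng.integers(1, 15))
    n_cols = int(rng.integers(1, max(2, max_cells // n_rows) + 1))
    shape = (n_rows, n_cols)
    n_sp = int(rng.integers(1, max_species + 1))
    n_hab = int(rng.integers(1, max_habitats + 1))
    A = {f"sp{k}": rng.random(shape) for k in range(n_sp)}
    H = {f"hab{k}": rng.random(shape) for k in range(n_hab)}
    w = {}
    for sp in A:
        for hab in H:
            if rng.random() < 0.7:
                w[(sp, hab)] = float(rng.random() * 5)
    return shape, A, H, w


def instance_stack(shape, H, grid=None):
    """Wrap raw layers into a HabitatCoverStack on a synthetic catalog."""
    from cimpal.habitats import HabitatType

    if grid is None:
        grid = build_grid((0.0, 0.0, shape[1] * 0.01, shape[0] * 0.01), 0.01)
    catalog = {
        hab: HabitatType(hab, hab, "shallow_0_60", "soft") for hab in H
    }
    mask = np.ones(shape, dtype=bool)
    return HabitatCoverStack(
        grid=grid, covers={h: v.copy() for h, v in H.items()}, study_mask=mask,
        catalog=catalog,
    )
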