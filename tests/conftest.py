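"""Shared fixtures: a small synthetic study and hand-built toys."""

import numpy as np
import pytest

from topoepi import (
    DEMGrid,
    SpatialWeights,
    SyntheticConfig,
    generate_study,
)
from topoepi.synthetic import voronoi_villages


def small_config(**overrides) -> SyntheticConfig:
    """A fast study: 60x60 grid, 80 villages, otherwise default physics."""
    base = dict(
        grid_rows=60,
        grid_cols=60,
        basin_center=(30.0, 30.0),
        basin_radius=16.0,
        n_villages=80,
        seed=11,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


@pytest.fixture(scope="session")
def default_study():
    """One full-size study under the default conditions."""
    return generate_study(SyntheticConfig(seed=5))


@pytest.fixture()
def path_weights():
    """5-village path graph: v1 - v2 - v3 - v4 - v5."""
    ids = [f"v{k}" for k in range(1, 6)]
    m = np.zeros((5, 5))
    for i in range(4):
        m[i, i + 1] = m[i + 1, i] = 1.0
    return SpatialWeights(ids, m)


@pytest.fixture()
def lattice_2x2_rook():
    """2x2 lattice of square villages with rook adjacency."""
    ids = ["a", "b", "c", "d"]  # row-major: a b / c d
    m = np.array(
        [
            [0, 1, 1, 0],
            [1, 0, 0, 1],
            [1, 0, 0, 1],
            [0, 1, 1, 0],
        ],
        dtype=float,
    )
    return SpatialWeights(ids, m, rule="rook")


def random_voronoi(rng: np.random.Generator, n: int, extent: float = 1000.0):
    """Voronoi villages of n random distinct points in a square box."""
    pts = rng.uniform(0.05 * extent, 0.95 * extent, size=(n, 2))
    return voronoi_villages(pts, (0.0, 0.0, extent, extent))


def constant_dem(rows=6, cols=6, value=1000.0, cell=100.0) -> DEMGrid:
    return DEMGrid(
        values=np.full((rows, cols), value),
        cell_size_m=cell,
        origin=(0.0, rows * cell),
    )
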