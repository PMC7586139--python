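import numpy as np
import pytest

from gumatrix import Lattice, map_projection_to_grid
from gumatrix.datasets import make_gaussian_mixture, make_linear_projection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_lattice():
    return Lattice(5, 7)


@pytest.fixture
def tiny_mixture():
    """Small 3-cluster dataset + PCA projection for fast pipeline tests."""
    ds = make_gaussian_mixture(k=3, n=120, d=3, separation=5.0, seed=7)
    return ds, make_linear_projection(ds.data)


def brute_force_uheights(weights: np.ndarray) -> np.ndarray:
    """Independent U-height oracle: explicit double loop over cells and
    their eight toroidal Moore neighbors."""
    from gumatrix import GridPosition, toroidal_neighbors

    lines, columns, _ = weights.shape
    lattice = Lattice(lines, columns)
    out = np.zeros((lines, columns))
    for line in range(1, lines + 1):
        for column in range(1, columns + 1):
            w = weights[line - 1, column - 1]
            dists = [
                np.linalg.norm(weights[nl - 1, nc - 1] - w)
                for nl, nc in toroidal_neighbors(GridPosition(line, column), lattice)
            ]
            out[line - 1, column - 1] = np.mean(dists)
    return out
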