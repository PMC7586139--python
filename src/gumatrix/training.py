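"""Simplified emergent SOM (sESOM) training.

Classical online SOM training needs a learning rate and an epoch count.
The simplified variant needs neither: the cooling scheme is carried
entirely by a parabolic neighborhood function

    h(d, R) = 1 - d^2 / (pi R^2)   if d^2 / (pi R^2) < 1, else 0

and the radius R simply steps down from Rmax = C/6 to 1, one unit per
step.  Each data point keeps its predefined BMU cell from the projection
(fgrid), but the BMU *search* is still performed at every presentation,
so prototypes elsewhere on the map can capture points while the map
unfolds.  After every radius step the predefined cells are reset to their
data points, anchoring the map to the projection.

The public entry point :func:`train_sesom` deliberately exposes no
learning rate, epoch count or radius — everything is derived from the
lattice, which is what makes the procedure parameter-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import GridPosition, Lattice, squared_distance_template
from .projection import BmuAssignment


@dataclass(frozen=True)
class TrainingConfig:
    """Run plumbing: the seed drives presentation-order shuffling and
    prototype initialization; the metric is the input-space distance D."""

    seed: int = 0
    distance_metric: str = "euclidean"


@dataclass
class PrototypeGrid:
    """The trained map: one d-dimensional prototype per lattice cell."""

    weights: np.ndarray  # (L, C, d)
    lattice: Lattice

    def __post_init__(self) -> None:
        expected = (self.lattice.lines, self.lattice.columns)
        if self.weights.ndim != 3 or self.weights.shape[:2] != expected:
            raise ValueError(
                f"weights must have shape {expected} x d, got {self.weights.shape}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("prototype weights must be finite")

    @property
    def dim(self) -> int:
        return self.weights.shape[2]

    def flat(self) -> np.ndarray:
        """(L*C, d) row-major view of the prototypes."""
        return self.weights.reshape(-1, self.weights.shape[2])


def _pointwise_distances(flat_weights: np.ndarray, x: np.ndarray, metric: str) -> np.ndarray:
    diff = flat_weights - x
    if metric == "euclidean":
        return np.einsum("ij,ij->i", diff, diff)  # squared; same argmin
    if metric == "cityblock":
        return np.abs(diff).sum(axis=1)
    if metric == "chebyshev":
        return np.abs(diff).max(axis=1)
    raise ValueError(f"unknown distance metric {metric!r}")


def neighborhood_h(d: float, R: float) -> float:
    """Parabolic neighborhood weight in [0, 1].

    Full pull (1) at the BMU itself, decaying to 0 at squared grid
    distance pi*R^2; the boundary itself falls into the zero branch.
    """
    if R <= 0:
        raise ValueError("neighborhood radius must be positive")
    q = (d * d) / (math.pi * R * R)
    return 1.0 - q if q < 1.0 else 0.0


def find_bmu(x: np.ndarray, grid: PrototypeGrid, metric: str = "euclidean") -> GridPosition:
    """Cell whose prototype is closest to ``x`` in input space.

    Ties go to the smallest (line, column) in lexicographic order, which
    is the first cell in row-major scan order.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (grid.dim,):
        raise ValueError(f"point has shape {x.shape}, prototypes have dim {grid.dim}")
    d = _pointwise_distances(grid.flat(), x, metric)
    idx = int(np.argmin(d))
    line, column = divmod(idx, grid.lattice.columns)
    return GridPosition(line + 1, column + 1)


def cooling_schedule(lattice: Lattice) -> np.ndarray:
    """Radii from Rmax = C/6 down to 1, step -1, always ending at 1.

    The final step may be fractional to land exactly on 1; tiny lattices
    with C/6 < 1 get the single-radius schedule [1].
    """
    rmax = max(lattice.columns / 6.0, 1.0)
    radii = list(np.arange(rmax, 1.0, -1.0))
    if not radii or radii[-1] != 1.0:
        radii.append(1.0)
    return np.asarray(radii)


def update_neighborhood(
    grid: PrototypeGrid,
    bmu: GridPosition,
    x: np.ndarray,
    R: float,
    _d2_template: np.ndarray | None = None,
) -> PrototypeGrid:
    """Pull every prototype in the BMU's neighborhood toward ``x``.

    In-place update ``w <- w + h * (x - w)``; the BMU cell (h = 1) is set
    to ``x`` exactly, cells outside the neighborhood are untouched
    bit-for-bit.  Returns the same grid for chaining.
    """
    if R < 1:
        raise ValueError("radius must be >= 1 during training")
    if not grid.lattice.contains(bmu):
        raise ValueError(f"BMU {bmu} outside the lattice")
    x = np.asarray(x, dtype=float)
    d2 = _d2_template if _d2_template is not None else squared_distance_template(grid.lattice)
    q = np.roll(d2, (bmu[0] - 1, bmu[1] - 1), axis=(0, 1)) / (math.pi * R * R)
    h = np.where(q < 1.0, 1.0 - q, 0.0)
    mask = h > 0.0
    w = grid.weights
    w[mask] += h[mask, None] * (x - w[mask])
    w[bmu[0] - 1, bmu[1] - 1] = x
    return grid


def _cell_means(data: np.ndarray, assignment: BmuAssignment) -> dict[GridPosition, np.ndarray]:
    """Reset targets: the mean data vector of each predefined cell."""
    return {
        cell: data[idx].mean(axis=0)
        for cell, idx in assignment.cell_members.items()
    }


def train_sesom(
    data: np.ndarray,
    assignment: BmuAssignment,
    lattice: Lattice,
    config: TrainingConfig = TrainingConfig(),
) -> PrototypeGrid:
    """Train the simplified ESOM and return the prototype grid.

    The loop steps the radius from Rmax down to 1.  At each radius every
    data point is presented once in seeded-shuffled order: its current
    BMU is searched globally, and the neighborhood around that BMU is
    pulled toward the point.  After the sweep, each predefined cell's
    prototype is reset to the mean of its assigned data points, so after
    the final step every occupied cell equals its data (mean) exactly.

    Non-predefined prototypes are initialized to data points sampled
    uniformly with the run seed, which keeps the map inside the data's
    support.  The run is fully deterministic given (data, assignment,
    seed).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("data must be a non-empty n x d matrix")
    if assignment.n_points != data.shape[0]:
        raise ValueError("assignment and data disagree on the number of points")
    if assignment.lattice != lattice:
        raise ValueError("assignment was computed for a different lattice")

    n, d = data.shape
    rng = np.random.default_rng(config.seed)

    init_idx = rng.integers(0, n, size=lattice.n_units)
    weights = data[init_idx].reshape(lattice.lines, lattice.columns, d).copy()
    grid = PrototypeGrid(weights=weights, lattice=lattice)

    means = _cell_means(data, assignment)

    def reset() -> None:
        for (line, column), mean in means.items():
            grid.weights[line - 1, column - 1] = mean

    reset()
    d2_template = squared_distance_template(lattice)
    for radius in cooling_schedule(lattice):
        order = rng.permutation(n)
        for i in order:
            x = data[i]
            bmu = find_bmu(x, grid, config.distance_metric)
            update_neighborhood(grid, bmu, x, float(radius), _d2_template=d2_template)
        reset()
    return grid
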