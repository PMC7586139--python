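"""End-to-end pipeline: data + projection -> topographic map.

This is the package's main entry point.  Given a high-dimensional data
matrix and any 2-D projection of it, the pipeline sizes the toroidal
lattice, fixes the BMUs from the projection, trains the simplified ESOM,
computes the generalized U-matrix, and derives the topographic map
(normalized heights, elevation classes and colors, contours, island
cut-out, valley count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import (
    DEFAULT_EMERGENCE_FLOOR,
    Lattice,
    compute_aspect_ratio,
    size_lattice,
    squared_distance_template,
)
from .projection import BmuAssignment, map_projection_to_grid
from .topography import (
    DEFAULT_SEA_LEVEL,
    HypsometricScale,
    colorize,
    count_valleys,
    cut_island,
    extract_contours,
    interval_count,
    robust_normalize,
    robust_percentiles,
    shift_positions,
    tile_toroidal,
)
from .training import PrototypeGrid, TrainingConfig, cooling_schedule, train_sesom
from .umatrix import UMatrix, compute_uheights


@dataclass
class TopographicMap:
    """Everything the pipeline computes, ready for rendering or export."""

    lattice: Lattice
    assignment: BmuAssignment
    prototypes: PrototypeGrid
    umatrix: UMatrix
    normalized: np.ndarray          # (L, C) in [0, 1]
    q01: float
    q99: float
    n_intervals: int
    color_class: np.ndarray         # (L, C) ints 1..n_intervals
    color_table: np.ndarray         # (n_intervals, 3) sRGB
    contours: list = field(repr=False)
    schedule: np.ndarray
    seed: int
    sea_level: float
    n_valleys: int
    island_offset: tuple[int, int] | None = None
    island_normalized: np.ndarray | None = None
    island_class: np.ndarray | None = None
    island_positions: np.ndarray | None = None  # BMUs re-indexed to the island

    @property
    def tiled_normalized(self) -> np.ndarray:
        """2L x 2C tiling: every receptive field shown four times."""
        return tile_toroidal(self.normalized)

    @property
    def tiled_class(self) -> np.ndarray:
        return tile_toroidal(self.color_class)


def compute_topographic_map(
    data: np.ndarray,
    projection: np.ndarray,
    seed: int = 0,
    sea_level: float = DEFAULT_SEA_LEVEL,
    emergence_floor: int = DEFAULT_EMERGENCE_FLOOR,
    metric: str = "euclidean",
    with_island: bool = True,
    scale: HypsometricScale | None = None,
) -> TopographicMap:
    """Run the full generalized U-matrix pipeline.

    Beyond the seed (presentation-order shuffling and prototype
    initialization) there is nothing to tune: the lattice size, radius
    schedule and interval count are all derived from the inputs.
    """
    data = np.asarray(data, dtype=float)
    projection = np.asarray(projection, dtype=float)
    if data.shape[0] != projection.shape[0]:
        raise ValueError(
            f"data has {data.shape[0]} points but projection has {projection.shape[0]}"
        )

    delta = compute_aspect_ratio(projection)
    lattice = size_lattice(delta, data.shape[0], emergence_floor)
    assignment = map_projection_to_grid(projection, lattice)
    config = TrainingConfig(seed=seed, distance_metric=metric)
    prototypes = train_sesom(data, assignment, lattice, config)
    umatrix = compute_uheights(prototypes, metric)

    q01, q99 = robust_percentiles(umatrix)
    normalized = robust_normalize(umatrix)
    n_intervals = interval_count(q01, q99)
    color_class, color_table = colorize(normalized, n_intervals, scale)
    contours = extract_contours(color_class)
    n_valleys = count_valleys(normalized, assignment, sea_level)

    result = TopographicMap(
        lattice=lattice,
        assignment=assignment,
        prototypes=prototypes,
        umatrix=umatrix,
        normalized=normalized,
        q01=q01,
        q99=q99,
        n_intervals=n_intervals,
        color_class=color_class,
        color_table=color_table,
        contours=contours,
        schedule=cooling_schedule(lattice),
        seed=seed,
        sea_level=sea_level,
        n_valleys=n_valleys,
    )
    if with_island:
        offset, island = cut_island(normalized, assignment)
        result.island_offset = offset
        result.island_normalized = island
        result.island_class, _ = colorize(island, n_intervals, scale)
        result.island_positions = shift_positions(assignment.positions, offset, lattice)
    return result


def boundary_height_contrast(
    result: TopographicMap,
    labels: np.ndarray,
) -> tuple[float, float]:
    """Mean normalized U-height under cross-class vs within-class pairs.

    Considers every unordered pair of data points whose BMU cells are
    within toroidal grid distance sqrt(2) of each other (same cell or
    Moore-adjacent): these are points the projection placed next to each
    other.  The pair's height is the mean normalized height of the two
    BMU cells.  If adjacent points from different classes sit on higher
    ground than adjacent same-class points, the map is exposing the
    projection's errors: neighbors in 2-D that are far apart in the
    input space.

    Returns ``(cross_mean, within_mean)``; either is NaN if no such pair
    exists.
    """
    labels = np.asarray(labels)
    pos = np.asarray(result.assignment.positions)  # (n, 2), 1-based
    lattice = result.lattice
    d2 = squared_distance_template(lattice)
    dl = (pos[:, None, 0] - pos[None, :, 0]) % lattice.lines
    dc = (pos[:, None, 1] - pos[None, :, 1]) % lattice.columns
    adjacent = d2[dl, dc] <= 2
    upper = np.triu(np.ones(len(pos), dtype=bool), k=1)
    heights = result.normalized[pos[:, 0] - 1, pos[:, 1] - 1]
    pair_height = 0.5 * (heights[:, None] + heights[None, :])
    cross = labels[:, None] != labels[None, :]

    cross_pairs = adjacent & upper & cross
    within_pairs = adjacent & upper & ~cross
    cross_mean = float(pair_height[cross_pairs].mean()) if cross_pairs.any() else float("nan")
    within_mean = float(pair_height[within_pairs].mean()) if within_pairs.any() else float("nan")
    return cross_mean, within_mean
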