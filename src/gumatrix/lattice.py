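"""Toroidal lattice geometry for emergent self-organizing maps.

An emergent SOM needs a large, cyclically connected (toroidal) grid of
neurons so that structure can emerge as a map rather than a direct
clustering.  This module sizes that grid from the bounding box of a 2-D
projection and provides the neighbor and distance primitives every later
stage builds on.

Conventions
-----------
Grid positions are 1-based ``(line, column)`` pairs.  Line 1 is the top
row of the map (largest projected y), column 1 the leftmost (smallest
projected x).  Because the lattice is a torus, opposite edges are
identified and every cell has exactly eight Moore neighbors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np

#: Smallest admissible side length: below 3 the eight-cell Moore
#: neighborhood degenerates (cells would neighbor themselves).
MIN_SIDE = 3

#: Default lower bound on the number of neurons.  Emergence requires a
#: large map (thousands of units, not one per cluster); 4096 = 64**2 is
#: used as a clean square default.
DEFAULT_EMERGENCE_FLOOR = 4096

_EPS = 1e-12

#: Offsets of the eight Moore neighbors, row-major order.
MOORE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


class GridPosition(NamedTuple):
    """1-based position of a neuron on the lattice."""

    line: int
    column: int


@dataclass(frozen=True)
class Lattice:
    """A toroidal grid of ``lines x columns`` neurons.

    Parameters
    ----------
    lines, columns
        Side lengths; both must be at least :data:`MIN_SIDE`.
    toroidal
        Always ``True``: the map's borders are cyclically connected so
        there are no boundary effects.  Kept as an explicit field so the
        assumption is visible in saved metadata.
    """

    lines: int
    columns: int
    toroidal: bool = True

    def __post_init__(self) -> None:
        if self.lines < MIN_SIDE or self.columns < MIN_SIDE:
            raise ValueError(
                f"lattice sides must be >= {MIN_SIDE}, got {self.lines}x{self.columns}"
            )
        if not self.toroidal:
            raise ValueError("only toroidal lattices are supported")

    # Short aliases used in formula-dense code.
    @property
    def L(self) -> int:  # noqa: N802 - conventional symbol
        return self.lines

    @property
    def C(self) -> int:  # noqa: N802 - conventional symbol
        return self.columns

    @property
    def n_units(self) -> int:
        return self.lines * self.columns

    def contains(self, pos: GridPosition) -> bool:
        return 1 <= pos[0] <= self.lines and 1 <= pos[1] <= self.columns

    def positions(self) -> Iterator[GridPosition]:
        """All grid positions in row-major order (line 1 first)."""
        for line in range(1, self.lines + 1):
            for column in range(1, self.columns + 1):
                yield GridPosition(line, column)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def compute_aspect_ratio(projection: np.ndarray) -> float:
    """Height/width ratio of the projection's bounding box.

    Returns ``delta = (max(y) - min(y)) / (max(x) - min(x))``.  If either
    extent is (numerically) zero the projection is degenerate along that
    axis and ``delta = 1`` is substituted so collinear projections still
    produce a square map.

    Raises
    ------
    ValueError
        If the projection has fewer than 2 points or is not ``n x 2``.
    """
    proj = np.asarray(projection, dtype=float)
    if proj.ndim != 2 or proj.shape[1] != 2:
        raise ValueError(f"projection must be an n x 2 matrix, got shape {proj.shape}")
    if proj.shape[0] < 2:
        raise ValueError("aspect ratio needs at least 2 projected points")
    dx = float(np.ptp(proj[:, 0]))
    dy = float(np.ptp(proj[:, 1]))
    if dx < _EPS or dy < _EPS:
        return 1.0
    return dy / dx


def size_lattice(
    delta: float,
    n_points: int,
    emergence_floor: int = DEFAULT_EMERGENCE_FLOOR,
) -> Lattice:
    """Choose the smallest lattice matching the projection's shape.

    Two conditions drive the size: (I) the lattice aspect ratio
    ``(L-1)/(C-1)`` should match the bounding-box ratio ``delta``, and
    (II) the number of neurons ``L*C`` must reach ``max(n_points,
    emergence_floor)`` so the map operates in the emergent regime.
    Solving the two conditions for L gives the closed-form lower bound

        L >= -(1 + delta)/2 + sqrt(((1 + delta)/2)**2 + NN * delta)

    L is the ceiling of that bound, C follows from condition (I) by
    half-up rounding, and C is then incremented if needed until
    condition (II) holds.
    """
    if delta <= 0 or not math.isfinite(delta):
        raise ValueError(f"aspect ratio must be a positive finite real, got {delta}")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    nn = max(int(n_points), int(emergence_floor))
    half = (1.0 + delta) / 2.0
    bound = -half + math.sqrt(half * half + nn * delta)
    lines = max(math.ceil(bound - _EPS), MIN_SIDE)
    columns = max(_round_half_up((lines - 1) / delta) + 1, MIN_SIDE)
    while lines * columns < nn:
        columns += 1
    return Lattice(lines, columns)


def toroidal_neighbors(m: GridPosition, lattice: Lattice) -> set[GridPosition]:
    """The eight Moore neighbors of ``m`` with cyclic wraparound."""
    if not lattice.contains(m):
        raise ValueError(f"position {m} outside {lattice.lines}x{lattice.columns} lattice")
    line, column = m
    out = set()
    for dl, dc in MOORE_OFFSETS:
        out.add(
            GridPosition(
                (line - 1 + dl) % lattice.lines + 1,
                (column - 1 + dc) % lattice.columns + 1,
            )
        )
    return out

def _wrapped_delta(a: int, b: int, extent: int) -> int:
    d = abs(a - b)
    return min(d, extent - d)


def toroidal_grid_distance(a: GridPosition, b: GridPosition, lattice: Lattice) -> float:
    """Minimum-image Euclidean distance between two cells on the torus."""
    if not lattice.contains(a) or not lattice.contains(b):
        raise ValueError("positions must lie within the lattice")
    dl = _wrapped_delta(a[0], b[0], lattice.lines)
    dc = _wrapped_delta(a[1], b[1], lattice.columns)
    return math.hypot(dl, dc)


def squared_distance_template(lattice: Lattice) -> np.ndarray:
    """Squared toroidal distances from cell (1,1) to every cell.

    ``template[(i - a) % L, (j - b) % C]`` is the squared grid distance
    between 0-based cells ``(a, b)`` and ``(i, j)``; rolling this array
    therefore gives the full distance field around any cell in O(L*C).
    """
    li = np.arange(lattice.lines)
    ci = np.arange(lattice.columns)
    dl = np.minimum(li, lattice.lines - li)
    dc = np.minimum(ci, lattice.columns - ci)
    return dl[:, None] ** 2 + dc[None, :] ** 2
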