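"""fgrid: map projected scatter-plot coordinates onto fixed lattice cells.

The defining trick of the simplified ESOM is that best-matching units are
not discovered during training but *assigned up front* from the 2-D
projection: each projected point is affinely rescaled into the lattice
coordinate system and snapped to the nearest cell.  Those cells stay the
point's "predefined" BMU for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import GridPosition, Lattice

_EPS = 1e-12


@dataclass
class BmuAssignment:
    """Result of fgrid: one lattice cell per data point.

    fgrid is a total function but not injective — several points may land
    in the same cell; ``cell_members`` records that multiplicity.
    """

    positions: np.ndarray  # (n, 2) int array of 1-based (line, column)
    lattice: Lattice
    cell_members: dict[GridPosition, list[int]] = field(repr=False)

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    def position_of(self, index: int) -> GridPosition:
        line, column = self.positions[index]
        return GridPosition(int(line), int(column))

    def occupied_cells(self) -> list[GridPosition]:
        return list(self.cell_members)


def _scale_axis(values: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1]; a zero-extent axis collapses to the middle."""
    lo = values.min()
    extent = values.max() - lo
    if extent < _EPS:
        return np.full(values.shape, 0.5)
    return (values - lo) / extent


def map_projection_to_grid(projection: np.ndarray, lattice: Lattice) -> BmuAssignment:
    """Assign every projected point its fixed best-matching unit.

    x is mapped affinely so ``min(x)`` hits column 1 and ``max(x)``
    column C; y so ``max(y)`` hits line 1 and ``min(y)`` line L (the map
    y-axis runs from line L at the bottom up to line 1, i.e. larger y is
    "up").  Fractional positions are rounded half-up and clamped into
    bounds, so the assignment is deterministic and invariant under any
    positive affine rescaling of the projection.
    """
    proj = np.asarray(projection, dtype=float)
    if proj.ndim != 2 or proj.shape[1] != 2:
        raise ValueError(f"projection must be an n x 2 matrix, got shape {proj.shape}")
    if proj.shape[0] < 1:
        raise ValueError("projection must contain at least one point")

    sx = _scale_axis(proj[:, 0])
    sy = _scale_axis(proj[:, 1])
    columns = np.floor(1 + sx * (lattice.columns - 1) + 0.5).astype(int)
    lines = np.floor(1 + (1.0 - sy) * (lattice.lines - 1) + 0.5).astype(int)
    columns = np.clip(columns, 1, lattice.columns)
    lines = np.clip(lines, 1, lattice.lines)

    positions = np.column_stack([lines, columns])
    members: dict[GridPosition, list[int]] = {}
    for i, (line, column) in enumerate(positions):
        members.setdefault(GridPosition(int(line), int(column)), []).append(i)
    return BmuAssignment(positions=positions, lattice=lattice, cell_members=members)
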