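"""Generalized U-matrix: U-heights over the trained toroidal prototype grid.

The U-height of a cell is the mean input-space distance between its
prototype and the prototypes of its eight Moore neighbors.  High cells
are cluster borders (neighboring prototypes far apart), low cells are
cluster interiors.  Because the grid is a torus, there is no border
special-casing — every cell has exactly eight neighbors by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import MOORE_OFFSETS, Lattice, MIN_SIDE
from .training import PrototypeGrid


@dataclass
class UMatrix:
    heights: np.ndarray  # (L, C), non-negative
    lattice: Lattice


def _offset_distances(weights: np.ndarray, dl: int, dc: int, metric: str) -> np.ndarray:
    diff = weights - np.roll(weights, (dl, dc), axis=(0, 1))
    if metric == "euclidean":
        return np.sqrt((diff * diff).sum(axis=-1))
    if metric == "cityblock":
        return np.abs(diff).sum(axis=-1)
    if metric == "chebyshev":
        return np.abs(diff).max(axis=-1)
    raise ValueError(f"unknown distance metric {metric!r}")


def compute_uheights(grid: PrototypeGrid, metric: str = "euclidean") -> UMatrix:
    """Mean distance from each prototype to its 8 toroidal neighbors."""
    lattice = grid.lattice
    if lattice.lines < MIN_SIDE or lattice.columns < MIN_SIDE:
        raise ValueError("U-heights need a lattice of at least 3x3")
    total = np.zeros((lattice.lines, lattice.columns))
    for dl, dc in MOORE_OFFSETS:
        total += _offset_distances(grid.weights, dl, dc, metric)
    return UMatrix(heights=total / len(MOORE_OFFSETS), lattice=lattice)


def save_uheights(umatrix: UMatrix, path) -> None:
    """Write heights as delimited text, L rows x C columns, line 1 first."""
    np.savetxt(path, umatrix.heights, delimiter="\t")


def load_uheights(path) -> np.ndarray:
    heights = np.loadtxt(path, delimiter="\t", ndmin=2)
    return heights
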