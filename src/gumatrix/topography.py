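"""Topographic-map construction from U-heights.

The U-heights are turned into a landscape the way cartographers draw
relief: robust normalization against the 1st/99th percentiles, binning
into elevation intervals, hypsometric tints (blue sea for small
distances, green/brown hills for middle ones, white peaks for large
ones), and black contour lines around contiguous same-interval regions.
Because the underlying map is a torus the landscape is displayed tiled
2x2, and a single L x C "island" window can be cut out automatically
along the mountains so no valley is severed.

Valleys — connected low regions that contain projected points — are the
map's estimate of the number of clusters in the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.color import lab2rgb, rgb2lab

from .lattice import Lattice
from .projection import BmuAssignment
from .umatrix import UMatrix

_EPS = 1e-12

#: Clamp bounds for the number of elevation intervals.
MIN_INTERVALS = 8
MAX_INTERVALS = 64

#: Default sea level on the normalized [0, 1] height scale; low regions
#: under this threshold count as valleys (clusters).
DEFAULT_SEA_LEVEL = 0.3


def _as_heights(heights) -> np.ndarray:
    if isinstance(heights, UMatrix):
        heights = heights.heights
    arr = np.asarray(heights, dtype=float)
    if arr.size == 0:
        raise ValueError("height array is empty")
    return arr


def robust_percentiles(heights) -> tuple[float, float]:
    """1st and 99th percentile of the U-heights (linear interpolation)."""
    arr = _as_heights(heights)
    q01, q99 = np.percentile(arr, [1, 99])
    return float(q01), float(q99)


def robust_normalize(heights) -> np.ndarray:
    """Normalize heights to [0, 1] against the 1st/99th percentiles.

    ``(u - q01) / (q99 - q01)``, clamped into [0, 1] so the tails beyond
    the robust range saturate at sea level / peak white.  A constant map
    (q01 == q99) normalizes to all zeros.
    """
    arr = _as_heights(heights)
    q01, q99 = robust_percentiles(arr)
    if q99 - q01 < _EPS:
        return np.zeros_like(arr)
    return np.clip((arr - q01) / (q99 - q01), 0.0, 1.0)


def interval_count(q01: float, q99: float, eps: float = _EPS) -> int:
    """Number of elevation intervals from the robust height range.

    ``ceil(q99 / q01)`` clamped into [MIN_INTERVALS, MAX_INTERVALS]:
    wide dynamic ranges get more intervals; degenerate percentiles are
    absorbed by the clamps.
    """
    if q99 < q01 or q01 < 0:
        raise ValueError("percentiles must satisfy 0 <= q01 <= q99")
    ratio = q99 / max(q01, eps)
    return int(np.clip(math.ceil(ratio), MIN_INTERVALS, MAX_INTERVALS))


@dataclass(frozen=True)
class HypsometricScale:
    """Elevation color ramp, interpolated perceptually in CIELab.

    Anchor positions/colors are rendering constants chosen to read like a
    topographic map: sea blues below ~0.15, shore and green hills through
    the mid range, brown high ground, and white peaks from ~0.8 up.
    """

    anchors: tuple[tuple[float, tuple[float, float, float]], ...] = (
        (0.00, (0.10, 0.18, 0.55)),
        (0.10, (0.15, 0.40, 0.80)),
        (0.15, (0.62, 0.82, 0.92)),
        (0.20, (0.30, 0.62, 0.28)),
        (0.45, (0.58, 0.70, 0.30)),
        (0.65, (0.55, 0.40, 0.20)),
        (0.80, (0.82, 0.80, 0.76)),
        (1.00, (1.00, 1.00, 1.00)),
    )

    def colors_at(self, t: np.ndarray) -> np.ndarray:
        """sRGB colors for normalized heights ``t`` in [0, 1]."""
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
        pos = np.array([p for p, _ in self.anchors])
        rgb = np.array([c for _, c in self.anchors])
        lab = rgb2lab(rgb.reshape(1, -1, 3)).reshape(-1, 3)
        out_lab = np.stack(
            [np.interp(t.ravel(), pos, lab[:, ch]) for ch in range(3)], axis=-1
        )
        out = lab2rgb(out_lab.reshape(1, -1, 3)).reshape(-1, 3)
        return np.clip(out, 0.0, 1.0).reshape(t.shape + (3,))


def colorize(
    normalized: np.ndarray,
    n_intervals: int,
    scale: HypsometricScale | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin normalized heights into elevation classes and color them.

    Returns ``(color_class, color_table)``: classes are 1-based integers
    (1 = lowest/sea, n_intervals = highest/white), monotone in height;
    the table holds one CIELab-interpolated sRGB color per class, taken
    at the class's interval midpoint.
    """
    if n_intervals < 1:
        raise ValueError("need at least one interval")
    scale = scale or HypsometricScale()
    norm = np.clip(np.asarray(normalized, dtype=float), 0.0, 1.0)
    classes = np.clip(np.floor(norm * n_intervals).astype(int) + 1, 1, n_intervals)
    midpoints = (np.arange(n_intervals) + 0.5) / n_intervals
    return classes, scale.colors_at(midpoints)


def extract_contours(color_class: np.ndarray) -> list[np.ndarray]:
    """Black outlines of maximal same-class regions (8-connectivity).

    Each maximal connected region of one elevation class is traced with
    marching squares into a closed polyline in (row, col) grid
    coordinates (0-based array indexing of the view passed in).  A
    uniform class array yields no contours.
    """
    arr = np.asarray(color_class)
    if arr.ndim != 2:
        raise ValueError("class array must be 2-D")
    contours: list[np.ndarray] = []
    if np.all(arr == arr.flat[0]):
        return contours
    labels = measure.label(arr, connectivity=2, background=-1)
    for region in range(1, labels.max() + 1):
        mask = (labels == region).astype(float)
        contours.extend(measure.find_contours(mask, 0.5))
    return contours


def tile_toroidal(arr: np.ndarray) -> np.ndarray:
    """2x2 replication of the map so every receptive field shows 4 times."""
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return np.tile(arr, (2, 2))
    return np.tile(arr, (2, 2) + (1,) * (arr.ndim - 2))


def shift_positions(positions: np.ndarray, offset: tuple[int, int], lattice: Lattice) -> np.ndarray:
    """Re-index 1-based (line, column) positions after a cyclic shift."""
    pos = np.asarray(positions)
    dl, dc = offset
    lines = (pos[:, 0] - 1 - dl) % lattice.lines + 1
    columns = (pos[:, 1] - 1 - dc) % lattice.columns + 1
    return np.column_stack([lines, columns])


def cut_island(
    normalized: np.ndarray,
    bmus: BmuAssignment | None = None,
) -> tuple[tuple[int, int], np.ndarray]:
    """Automatically cut one L x C island out of the tiled display.

    Every L x C window of the 2L x 2C tiling is a cyclic shift of the
    torus, so each receptive field (and hence every BMU) appears in the
    window exactly once regardless of the offset.  The offset is chosen
    to maximize the total height along the window border: the cut runs
    through mountains and leaves valleys intact.  Ties go to the first
    offset in row-major scan order.

    Returns ``((dl, dc), cropped)`` where ``cropped[i, j] =
    normalized[(i + dl) % L, (j + dc) % C]``.
    """
    m = np.asarray(normalized, dtype=float)
    if m.ndim != 2:
        raise ValueError("normalized map must be 2-D")
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    row_term = row + np.roll(row, 1)  # border rows a and a-1
    col_term = col + np.roll(col, 1)  # border cols b and b-1
    corners = (
        m
        + np.roll(m, 1, axis=1)
        + np.roll(m, 1, axis=0)
        + np.roll(m, (1, 1), axis=(0, 1))
    )
    objective = row_term[:, None] + col_term[None, :] - corners
    dl, dc = np.unravel_index(int(np.argmax(objective)), m.shape)
    return (int(dl), int(dc)), np.roll(m, (-dl, -dc), axis=(0, 1))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def toroidal_label(mask: np.ndarray) -> np.ndarray:
    """8-connected component labels of a boolean mask on the torus.

    skimage labels the planar array; components touching across the
    wrap-around seams (including diagonally) are then merged.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    n = labels.max()
    if n == 0:
        return labels
    uf = _UnionFind(n + 1)
    rows, cols = mask.shape
    for j in range(cols):
        for dj in (-1, 0, 1):
            if mask[0, j] and mask[rows - 1, (j + dj) % cols]:
                uf.union(labels[0, j], labels[rows - 1, (j + dj) % cols])
    for i in range(rows):
        for di in (-1, 0, 1):
            if mask[i, 0] and mask[(i + di) % rows, cols - 1]:
                uf.union(labels[i, 0], labels[(i + di) % rows, cols - 1])
    remap = np.array([uf.find(k) for k in range(n + 1)])
    return remap[labels]


def count_valleys(
    normalized: np.ndarray,
    bmus: BmuAssignment,
    sea_level: float = DEFAULT_SEA_LEVEL,
) -> int:
    """Number of valleys: the map's estimate of the number of clusters.

    The toroidal map is thresholded at ``sea_level``; each 8-connected
    low component that contains at least one BMU (i.e. at least one
    projected point) counts as one valley.  Low components without data
    are empty basins, not clusters; maps with no cells below sea level
    have no distance-based structure and yield 0.
    """
    norm = np.asarray(normalized, dtype=float)
    labels = toroidal_label(norm < sea_level)
    occupied = {
        labels[line - 1, column - 1]
        for line, column in np.asarray(bmus.positions)
    }
    occupied.discard(0)
    return len(occupied)
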