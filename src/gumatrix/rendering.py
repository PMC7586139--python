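"""Raster export of the topographic map.

Draws the hypsometric-tinted landscape with black contour lines and one
marker per data point at its BMU (colored by class labels if given), and
writes it to PNG.  The island view shows the automatically cut L x C
window; the tiled view shows the full 2L x 2C toroidal tiling.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .pipeline import TopographicMap
from .topography import extract_contours, tile_toroidal


def _class_image(color_class: np.ndarray, color_table: np.ndarray) -> np.ndarray:
    return color_table[color_class - 1]


def render(
    result: TopographicMap,
    path: str | Path,
    labels: np.ndarray | None = None,
    view: str = "island",
    dpi: int = 150,
) -> Path:
    """Write the topographic map to ``path`` as a PNG; returns the path.

    ``view`` is ``"island"`` (default; falls back to the base map if no
    island was cut) or ``"tiled"``.  With ``labels``, BMU markers are
    colored per class; without, they are uniform dark dots.
    """
    if view == "tiled":
        classes = tile_toroidal(result.color_class)
        pos = np.asarray(result.assignment.positions)
        positions = np.vstack([pos + shift for shift in (
            (0, 0),
            (0, result.lattice.columns),
            (result.lattice.lines, 0),
            (result.lattice.lines, result.lattice.columns),
        )])
        point_labels = None if labels is None else np.tile(np.asarray(labels), 4)
        contours = extract_contours(classes)
    elif view == "island":
        if result.island_class is not None:
            classes = result.island_class
            positions = np.asarray(result.island_positions)
        else:
            classes = result.color_class
            positions = np.asarray(result.assignment.positions)
        point_labels = None if labels is None else np.asarray(labels)
        contours = extract_contours(classes)
    else:
        raise ValueError(f"unknown view {view!r}; use 'island' or 'tiled'")

    image = _class_image(classes, result.color_table)
    rows, cols = classes.shape
    fig, ax = plt.subplots(figsize=(max(cols / 16, 3), max(rows / 16, 3)))
    ax.imshow(image, interpolation="nearest", origin="upper")
    for contour in contours:
        ax.plot(contour[:, 1], contour[:, 0], color="black", linewidth=0.5)
    if point_labels is None:
        ax.scatter(positions[:, 1] - 1, positions[:, 0] - 1, s=6, c="#222222")
    else:
        cmap = plt.get_cmap("tab10")
        classes_present = np.unique(point_labels)
        for j, cls in enumerate(classes_present):
            sel = point_labels == cls
            ax.scatter(
                positions[sel, 1] - 1,
                positions[sel, 0] - 1,
                s=8,
                color=cmap(j % 10),
                label=str(cls),
            )
        ax.legend(loc="upper right", fontsize="x-small", title="class")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_xlim(-0.5, cols - 0.5)
    ax.set_ylim(rows - 0.5, -0.5)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path
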