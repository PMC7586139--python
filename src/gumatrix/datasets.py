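"""Synthetic benchmark datasets with known cluster structure.

These generators emulate the classic demonstration sets used to probe
projection quality: Chainlink (two interlocked 3-D rings — linearly
non-separable, so any linear projection must overlay parts of different
rings), an Lsun3D-like set (three compact clusters plus four distant
outliers), Golfball (uniform points on a sphere surface — no
distance-based cluster structure at all), and separable spherical
Gaussian mixtures with controlled separation.  Each comes with a simple
deterministic PCA projection fixture so the whole pipeline is testable
without external data.

The Lsun3D-like and Golfball generators are structurally equivalent
stand-ins built here, not copies of the original FCPS coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LabeledDataset:
    data: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) integers 1..k
    name: str
    seed: int

    @property
    def n_points(self) -> int:
        return self.data.shape[0]

    @property
    def dim(self) -> int:
        return self.data.shape[1]


def make_chainlink(n: int = 800, noise_sd: float = 0.05, seed: int = 0) -> LabeledDataset:
    """Two interlocked unit rings in orthogonal 3-D planes.

    Ring 1 lies in the x-y plane centered at the origin; ring 2 in the
    x-z plane centered at (1, 0, 0), so each ring passes through the
    other's hole.  ``n/2`` points per ring at uniform random angles, plus
    isotropic Gaussian noise of standard deviation ``noise_sd``.
    """
    if n < 20:
        raise ValueError("chainlink needs n >= 20")
    if n % 2:
        raise ValueError("chainlink needs an even n (two equal rings)")
    rng = np.random.default_rng(seed)
    half = n // 2
    t1 = rng.uniform(0, 2 * np.pi, half)
    t2 = rng.uniform(0, 2 * np.pi, half)
    ring1 = np.column_stack([np.cos(t1), np.sin(t1), np.zeros(half)])
    ring2 = np.column_stack([1 + np.cos(t2), np.zeros(half), np.sin(t2)])
    data = np.vstack([ring1, ring2])
    if noise_sd > 0:
        data = data + rng.normal(0, noise_sd, data.shape)
    labels = np.repeat([1, 2], half)
    return LabeledDataset(data, labels, "chainlink", seed)


def make_lsun3d_like(seed: int = 0) -> LabeledDataset:
    """Three compact 3-D clusters plus exactly four distant outliers.

    Two elongated bars (classes 1-2), one spherical blob (class 3), and
    four outlier points (class 4) placed far outside every cluster, so
    the minimum outlier-to-cluster-center distance exceeds any
    within-cluster radius by construction.
    """
    rng = np.random.default_rng(seed)
    bar1 = rng.normal(0, 1, (100, 3)) * [0.15, 0.8, 0.15] + [0.0, 1.0, 0.0]
    bar2 = rng.normal(0, 1, (100, 3)) * [0.8, 0.15, 0.15] + [1.0, -1.5, 0.0]
    blob = rng.normal(0, 0.3, (200, 3)) + [4.0, 4.0, 1.0]
    outliers = np.array(
        [
            [12.0, 12.0, 9.0],
            [-12.0, 12.0, -9.0],
            [12.0, -12.0, 9.0],
            [-12.0, -12.0, -9.0],
        ]
    )
    data = np.vstack([bar1, bar2, blob, outliers])
    labels = np.concatenate(
        [np.full(100, 1), np.full(100, 2), np.full(200, 3), np.full(4, 4)]
    )
    return LabeledDataset(data, labels, "lsun3d_like", seed)


def make_golfball(n: int = 500, seed: int = 0) -> LabeledDataset:
    """Points uniform on the unit sphere surface: no cluster structure.

    Normalized Gaussian triples; a single label class.
    """
    if n < 50:
        raise ValueError("golfball needs n >= 50")
    rng = np.random.default_rng(seed)
    pts = rng.normal(0, 1, (n, 3))
    norms = np.linalg.norm(pts, axis=1)
    while np.any(norms < 1e-12):  # pragma: no cover - measure-zero event
        bad = norms < 1e-12
        pts[bad] = rng.normal(0, 1, (bad.sum(), 3))
        norms = np.linalg.norm(pts, axis=1)
    data = pts / norms[:, None]
    return LabeledDataset(data, np.ones(n, dtype=int), "golfball", seed)


def _simplex_centers(k: int, d: int, separation: float) -> np.ndarray:
    """k cluster centers in R^d at pairwise distance = separation."""
    if k == 1:
        return np.zeros((1, d))
    if k > d + 1:
        raise ValueError(f"cannot place {k} equidistant centers in {d} dimensions")
    v = np.eye(k) - 1.0 / k  # regular simplex, edge sqrt(2), rank k-1
    u, s, _ = np.linalg.svd(v, full_matrices=False)
    coords = (u[:, : k - 1] * s[: k - 1]) * (separation / np.sqrt(2.0))
    centers = np.zeros((k, d))
    centers[:, : k - 1] = coords
    return centers


def make_gaussian_mixture(
    k: int,
    n: int,
    d: int = 3,
    separation: float = 5.0,
    cluster_sd: float = 0.05,
    seed: int = 0,
) -> LabeledDataset:
    """k spherical Gaussians with centers at pairwise distance ``separation``.

    Centers sit on a regular simplex (so k <= d + 1); ``separation = 0``
    collapses all centers to the origin.  Cluster sizes are as equal as n
    allows.
    """
    if k < 1:
        raise ValueError("need k >= 1 clusters")
    if n < k:
        raise ValueError("need at least one point per cluster")
    rng = np.random.default_rng(seed)
    centers = _simplex_centers(k, d, separation)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    data = np.vstack(
        [rng.normal(0, cluster_sd, (size, d)) + centers[j] for j, size in enumerate(sizes)]
    )
    labels = np.repeat(np.arange(1, k + 1), sizes)
    return LabeledDataset(data, labels, f"gaussian_mixture_k{k}", seed)


def make_linear_projection(data: np.ndarray) -> np.ndarray:
    """First two principal-component scores of the centered data.

    Deterministic sign convention: each component's largest-magnitude
    loading is made positive.  This is the simple linear-projection
    fixture the pipeline's inputs are tested with; any external
    projection method can be substituted.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("projection fixture needs n x d data with d >= 2")
    centered = x - x.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("data is constant; principal axes undefined")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for comp in range(2):
        pivot = np.argmax(np.abs(vt[comp]))
        if vt[comp, pivot] < 0:
            u[:, comp] = -u[:, comp]
            vt[comp] = -vt[comp]
    return u[:, :2] * s[:2]


def write_dataset(
    dataset: LabeledDataset,
    out_dir: str | Path,
    projection: np.ndarray | None = None,
) -> None:
    """Write data.csv (header f1..fd), labels.csv and optionally proj.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [f"f{j + 1}" for j in range(dataset.dim)]
    pd.DataFrame(dataset.data, columns=cols).to_csv(out / "data.csv", index=False)
    pd.DataFrame({"label": dataset.labels}).to_csv(out / "labels.csv", index=False)
    if projection is not None:
        pd.DataFrame(np.asarray(projection), columns=["x", "y"]).to_csv(
            out / "proj.csv", index=False
        )
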