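# gumatrix

Topographic maps that show what a 2-D projection of high-dimensional data
is hiding.

Dimensionality-reduction methods (PCA, t-SNE, UMAP, MDS, ...) compress a
dataset of n points in d dimensions into a 2-D scatter plot. The
Johnson–Lindenstrauss lemma guarantees that two dimensions cannot in
general carry the high-dimensional distances, so every such scatter plot
contains errors: points drawn side by side that are far apart in the
input space, and apparent gaps that do not exist. `gumatrix` takes the
dataset **and** its projection and computes the **generalized U-matrix**:
a landscape over a toroidal neuron lattice in which valleys are genuine
high-dimensional clusters, mountain ridges are cluster borders, and
hills between adjacent points expose the projection's misplacements.
Typical users are anyone who interprets embedding scatter plots —
biomarker panels, omics embeddings, single-cell maps — and wants to know
which visual structure is real.

## Method

Given data `X ∈ R^{n×d}` and a projection `P ∈ R^{n×2}`:

1. **Lattice sizing.** A toroidal grid of `L × C` neurons is sized so
   that `(L−1)/(C−1) ≈ Δ` (the projection's bounding-box aspect ratio)
   and `L·C ≥ max(n, 4096)` — thousands of neurons, because the map
   works in the *emergent* regime, not one-neuron-per-cluster. The
   closed form `L ≥ −(1+Δ)/2 + sqrt(((1+Δ)/2)² + n·Δ)` solves both
   conditions.
2. **fgrid.** Each projected point is affinely snapped to a lattice cell
   — its fixed best-matching unit (BMU).
3. **sESOM training.** A simplified emergent self-organizing map with no
   learning rate and no epochs: the radius steps from `Rmax = C/6` down
   to 1, and at each radius every point is presented once, pulling the
   neighborhood of its current BMU toward it with the parabolic weight
   `h = 1 − d²/(πR²)` (else 0). After every radius step the predefined
   BMU cells are reset to their data vectors, anchoring the map to the
   projection.
4. **U-heights.** Each cell's height is the mean input-space distance
   between its prototype and its 8 toroidal neighbors' prototypes
   (`u(j) = 1/8 Σ_{i∈N(j)} D(w_i, w_j)`).
5. **Topographic display.** Heights are robustly normalized against the
   1st/99th percentiles, binned into elevation intervals, colored with
   CIELab-interpolated hypsometric tints (blue sea → green/brown hills →
   white peaks), contoured, tiled 2×2 (the map is a torus), and an
   island is cut out automatically along the mountains. The number of
   valleys — connected low regions containing data — estimates the
   number of clusters.

## Worked example

Generate a separable 3-cluster Gaussian mixture with its PCA projection,
then compute the map:

```bash
gumatrix synth mixture --n 900 --k 3 --seed 42 --out-dir demo
gumatrix compute --data demo/data.csv --projection demo/proj.csv \
    --labels demo/labels.csv --out-dir demo/out --seed 42
```

Output:

```
lattice: 61 lines x 68 columns (4148 neurons)
cooling schedule: Rmax=11.333 in 12 steps down to 1
seed: 42 | valleys (clusters): 3
valleys: 3
```

The lattice was sized from the projection's aspect ratio and the
emergence floor (61·68 = 4148 ≥ 4096 neurons); the cooling schedule is
derived from the lattice (`Rmax = 68/6 ≈ 11.33`), so nothing was tuned;
and the map finds **3 valleys** — the true number of clusters.
`demo/out/` contains the raw U-heights (`umatrix.txt`), the normalized
heights, the BMU table, a JSON summary, and `topographic_map.png`, the
rendered island with one marker per data point colored by class.

The same pipeline is available as a library:

```python
from gumatrix import compute_topographic_map
from gumatrix.datasets import make_chainlink, make_linear_projection

ds = make_chainlink(n=800, seed=0)            # two interlocked 3-D rings
proj = make_linear_projection(ds.data)        # PCA: rings overlap in 2-D
result = compute_topographic_map(ds.data, proj, seed=0)
result.n_valleys, result.normalized            # valley count, L×C heights
```

On Chainlink the projection necessarily overlays the two rings; the map
shows the overlap as high ground between adjacent points from different
rings — the projection error is visible even though the scatter plot
hides it.

## Scope

The projection method itself is an input, never computed here (the
bundled PCA fixture exists only for self-contained examples and tests).
Density-weighted U*-matrix scaling, interactive island editing, and 3-D
printing outputs are out of scope; see `docs/methods.md` for the model
details, parameter defaults, and known limitations.
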