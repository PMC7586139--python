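# Methods

## Model

The generalized U-matrix renders the high-dimensional distance structure
of a dataset `X ∈ R^{n×d}` *as seen through* a given 2-D projection
`P ∈ R^{n×2}`. The projection fixes where each point sits on a neuron
lattice; a simplified emergent self-organizing map (sESOM) then learns
prototypes for every lattice cell; the per-cell mean distance to the
eight neighboring prototypes (the U-height) measures how much input-space
distance the projection squeezed into that patch of the plane. Low
regions (valleys) are cluster interiors, ridges are cluster borders, and
high ground between points the projection drew side by side exposes
projection errors.

Assumptions worth stating:

- The lattice is **toroidal** (edges cyclically identified). This removes
  border effects entirely; the cost is that the display must be tiled
  2×2 and an island cut out for reading.
- The map operates in the **emergent regime**: thousands of neurons
  (floor 4096 by default) regardless of n. With few neurons the map
  degenerates toward a k-means-style clustering and valleys merge; the
  test suite demonstrates this on purpose with a sub-emergent floor.
- Distances are Euclidean by default (`cityblock` and `chebyshev` are
  available). The same metric is used for BMU search, training, and
  U-heights.

## Lattice sizing

Conditions: (I) `(L−1)/(C−1) ≈ Δ` with
`Δ = (max(y)−min(y))/(max(x)−min(x))`, and (II)
`L·C ≥ NN = max(n, emergence_floor)`. These are solved as
`L = ceil(−(1+Δ)/2 + sqrt(((1+Δ)/2)² + NN·Δ))`,
`C = round((L−1)/Δ) + 1`, with C incremented until (II) holds. The
rounding rule gives the smallest lattice meeting both conditions; sides
below 3 are forbidden (the 8-cell Moore neighborhood would degenerate).
A degenerate bounding box (zero extent on either axis) falls back to
Δ = 1 so collinear projections still produce a map. The quadratic
`L² + L(1+Δ) − NN·Δ ≥ 0` is the form the closed-form bound solves;
condition (II) is enforced independently by the C bump, so the sizing
never relies on the quadratic alone.

## fgrid

x is mapped affinely so `min(x) → column 1`, `max(x) → column C`; y so
`max(y) → line 1` (top) and `min(y) → line L`. Fractional positions are
rounded half-up and clamped. Consequences documented because they are
classic foot-guns: the assignment is invariant under positive affine
rescaling of the projection; image row order (line 1 = top) is fixed
here once so maps never come out flipped; collisions (several points in
one cell) are retained, and such a cell's reset target is the mean of
its members. A zero-extent axis maps all points to the middle
line/column of that axis.

## sESOM training

No learning rate, no epoch count, no free radius: the schedule is
`Rmax = C/6, Rmax−1, …, 1` (final step fractional if needed; lattices
with C < 6 get the single-radius schedule `[1]`). Per radius step each
point is presented once in seeded-shuffled order; its BMU is found by
global argmin over all prototypes (ties to the first cell in row-major
order); the update is `w ← w + h·(x − w)` with
`h = 1 − d²/(πR²)` for `d² < πR²` on the toroidal grid distance, else 0.
The BMU cell is set to x exactly. After each radius step every
predefined (fgrid) cell is reset to the mean of its assigned points, so
the final map interpolates the data exactly at occupied cells.

Choices where the procedure was genuinely open:

- **Initialization** of non-predefined prototypes: data points sampled
  uniformly with the run seed. This keeps prototypes inside the data's
  support and makes the whole run reproducible from one integer.
- **Presentation order**: re-shuffled per radius step (online-SOM
  convention; deterministic given the seed).
- **One "iteration" = one radius step**; the reset happens after each
  radius step, and only fgrid cells are reset (cells captured during the
  BMU re-search are not).
- `Rmax` is clamped to ≥ 1 so tiny lattices still train one pass.

## U-heights and the topographic display

`u(j)` = mean Euclidean distance between cell j's prototype and its 8
toroidal Moore neighbors' prototypes; computed by rolled array
differences, verified against a brute-force double loop in the tests.
Heights are non-negative, zero exactly on locally constant patches,
cyclic-shift equivariant, and scale-covariant.

Display arithmetic:

- **Robust normalization**: `(u − q01)/(q99 − q01)` with linear-
  interpolation percentiles, clamped to [0, 1] (the clamp keeps the tails
  inside the color ramp; a constant map normalizes to zeros).
- **Interval count**: `ceil(q99/q01)` clamped into [8, 64] — a wider
  robust dynamic range earns more elevation classes; the clamps absorb
  degenerate percentiles (q01 = 0 → 64, q01 = q99 → 8).
- **Colors**: elevation classes are mapped to a blue→green→brown→white
  ramp interpolated in CIELab for perceptual uniformity. The anchor
  positions (sea below ~0.15, shore, green hills, brown high ground,
  white from ~0.8) are rendering constants, not model quantities.
- **Contours**: maximal 8-connected same-class regions are traced with
  marching squares.
- **Tiling and island**: the torus is displayed as a 2×2 tiling (each
  receptive field appears exactly four times). The island is the L×C
  cyclic window whose border has maximal total height — the cut runs
  through mountains, never through a valley; every cell appears in the
  window exactly once, so no data is lost. Ties go to the first offset
  in scan order.
- **Valleys**: the normalized toroidal map is thresholded at
  `sea_level = 0.3`; each 8-connected low component containing at least
  one BMU counts as one valley. The default threshold sits just above
  the ramp's sea/shore classes so that "blue" regions are what gets
  counted; it is exposed as a parameter.

## Synthetic fixtures

The generators emulate classic projection-quality benchmarks:

- **Chainlink** — two interlocked unit rings in orthogonal planes
  (n = 800 and Gaussian noise σ = 0.05 by default), linearly
  non-separable by construction, so any linear projection must place
  points from different rings side by side. This is the precondition
  for the projection-error demonstration, and the tests assert it (some
  cross-ring 2-D pair closer than the 5th percentile of within-ring 2-D
  distances).
- **Lsun3D-like** — two elongated bars, one spherical blob, and exactly
  four far outliers (404 points). A structural stand-in, not the
  original FCPS coordinates, hence the "-like".
- **Golfball** — n points uniform on the unit sphere (normalized
  Gaussian triples): distance structure without clusters.
- **Gaussian mixtures** — k spherical Gaussians (σ = 0.05 by default)
  with centers on a regular simplex at pairwise distance `separation`;
  the controlled testbed for valley recovery.
- **PCA fixture** — first two principal-component scores with a
  deterministic sign convention; stands in for an external projection.

What the fixtures do *not* emulate: real measurement noise structure,
unequal cluster sizes/anisotropy, very high ambient dimension, and
nonlinear projections' characteristic distortions. Passing tests on
these fixtures show the pipeline recovers planted distance structure
through a linear projection; they do not certify behavior on any
particular real embedding method.

## Numerical notes

- All randomness flows from one `numpy` `default_rng(seed)`; identical
  inputs and seed give bit-identical prototype grids.
- BMU ties break to the smallest (line, column); exact prototype
  duplicates therefore resolve deterministically.
- The neighborhood boundary `d² = πR²` belongs to the zero branch; since
  grid distances squared are integers and π is irrational, the boundary
  is never hit during training.
- Problem sizes used in the shipped checks (mixture n = 900, d = 3,
  separation 5; Golfball n = 500; Chainlink n = 800; 10 seeds per rate)
  are the package's standard demonstration conditions; a full pipeline
  run at the default 4096-neuron floor takes a few seconds.

## Known limitations

- **Structure-free data fragments the sea.** Robust normalization always
  stretches some region of the map to ~0, so a fixed relative sea level
  marks roughly the lowest third of *any* map as sea. On data with no
  cluster structure (Golfball) the sea consists of one dominant
  component holding most points plus several small data-bearing ponds,
  so the raw valley count overstates the structure (typically ~10
  instead of ≤1). The dominant-component structure is still diagnostic
  (one valley holds ~half the data, the rest hold a few points each),
  but the plain count should not be read as a cluster number for
  unstructured data. Density-weighted U*-heights would likely suppress
  these ponds; the density estimator is out of scope here.
- Valley counting is threshold-based, not watershed-based; nested or
  shallow valleys separated by low saddles may merge.
- The island cut optimizes border height only; it cannot rotate the map,
  and a valley larger than half the lattice in either direction may
  still touch the border.
- `fgrid` can stack many points in one cell when the projection is
  highly concentrated; the map then under-represents that region's
  internal structure.
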