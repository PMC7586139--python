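import math

import numpy as np
import pytest

from gumatrix import (
    GridPosition,
    Lattice,
    PrototypeGrid,
    TrainingConfig,
    cooling_schedule,
    find_bmu,
    map_projection_to_grid,
    neighborhood_h,
    train_sesom,
)
from gumatrix.training import update_neighborhood


class TestNeighborhoodFunction:
    def test_full_pull_at_zero_distance(self):
        assert neighborhood_h(0.0, 5.0) == 1.0

    def test_case_split_at_the_boundary(self):
        """h is positive strictly inside d^2 < pi R^2 and zero from the
        boundary outward."""
        r = 2.0
        boundary = math.sqrt(math.pi) * r
        assert neighborhood_h(boundary * (1 + 1e-9), r) == 0.0
        assert neighborhood_h(boundary * 1.5, r) == 0.0
        assert neighborhood_h(boundary * (1 - 1e-9), r) > 0.0

    def test_unit_distance_unit_radius(self):
        assert neighborhood_h(1.0, 1.0) == pytest.approx(1 - 1 / math.pi, abs=1e-12)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_h(1.0, 0.0)

    def test_range_and_monotonicity(self):
        r = 3.0
        values = [neighborhood_h(d, r) for d in np.linspace(0, 10, 200)]
        assert all(0.0 <= v <= 1.0 for v in values)
        assert np.all(np.diff(values) <= 1e-15)


class TestFindBmu:
    def test_exact_prototype_wins(self, rng):
        lattice = Lattice(4, 4)
        weights = rng.normal(size=(4, 4, 3))
        x = weights[2, 1].copy()
        assert find_bmu(x, PrototypeGrid(weights, lattice)) == (3, 2)

    def test_all_identical_ties_to_first_cell(self):
        grid = PrototypeGrid(np.ones((4, 5, 2)), Lattice(4, 5))
        assert find_bmu(np.array([9.0, 9.0]), grid) == (1, 1)

    def test_matches_exhaustive_scan(self, rng):
        lattice = Lattice(4, 4)
        for _ in range(25):
            weights = rng.normal(size=(4, 4, 3))
            grid = PrototypeGrid(weights, lattice)
            x = rng.normal(size=3)
            best = min(
                ((line, column) for line in range(1, 5) for column in range(1, 5)),
                key=lambda lc: (
                    float(np.sum((weights[lc[0] - 1, lc[1] - 1] - x) ** 2)),
                    lc,
                ),
            )
            assert tuple(find_bmu(x, grid)) == best

    def test_dimension_mismatch_rejected(self):
        grid = PrototypeGrid(np.zeros((3, 3, 2)), Lattice(3, 3))
        with pytest.raises(ValueError):
            find_bmu(np.zeros(3), grid)


class TestUpdateNeighborhood:
    def test_hand_traced_3x3(self):
        """All-zero 3x3 grid, x=(1,0), R=1: the BMU becomes x exactly,
        unit-distance cells get h = 1 - 1/pi, diagonal cells h = 1 - 2/pi."""
        lattice = Lattice(3, 3)
        grid = PrototypeGrid(np.zeros((3, 3, 2)), lattice)
        x = np.array([1.0, 0.0])
        update_neighborhood(grid, GridPosition(2, 2), x, 1.0)
        w = grid.weights
        assert np.array_equal(w[1, 1], x)
        h1 = 1 - 1 / math.pi
        h2 = 1 - 2 / math.pi
        for line, column in [(0, 1), (2, 1), (1, 0), (1, 2)]:
            assert w[line, column] == pytest.approx([h1, 0.0], abs=1e-15)
        for line, column in [(0, 0), (0, 2), (2, 0), (2, 2)]:
            assert w[line, column] == pytest.approx([h2, 0.0], abs=1e-15)

    def test_cells_outside_radius_bit_identical(self, rng):
        lattice = Lattice(9, 9)
        weights = rng.normal(size=(9, 9, 2))
        before = weights.copy()
        grid = PrototypeGrid(weights, lattice)
        update_neighborhood(grid, GridPosition(1, 1), np.array([5.0, 5.0]), 1.0)
        # pi R^2 = pi: only squared grid distances 0, 1, 2 are inside
        from gumatrix import toroidal_grid_distance

        for pos in lattice.positions():
            d = toroidal_grid_distance(GridPosition(1, 1), pos, lattice)
            w = grid.weights[pos.line - 1, pos.column - 1]
            if d * d >= math.pi:
                assert np.array_equal(w, before[pos.line - 1, pos.column - 1])
            else:
                assert not np.array_equal(w, before[pos.line - 1, pos.column - 1])

    def test_radius_below_one_rejected(self):
        grid = PrototypeGrid(np.zeros((3, 3, 1)), Lattice(3, 3))
        with pytest.raises(ValueError):
            update_neighborhood(grid, GridPosition(1, 1), np.zeros(1), 0.5)


class TestCoolingSchedule:
    def test_starts_at_c_over_6_ends_at_one(self):
        radii = cooling_schedule(Lattice(50, 64))
        assert radii[0] == pytest.approx(64 / 6)
        assert radii[-1] == 1.0
        assert np.all(np.diff(radii)[:-1] == pytest.approx(-1.0))
        assert np.all(np.diff(radii) < 0)

    def test_tiny_lattice_gets_single_pass(self):
        assert list(cooling_schedule(Lattice(3, 4))) == [1.0]

    def test_integral_rmax_has_no_duplicate_tail(self):
        radii = cooling_schedule(Lattice(10, 24))  # Rmax = 4 exactly
        assert list(radii) == [4.0, 3.0, 2.0, 1.0]


def _reference_train(data, assignment, lattice, seed):
    """Naive reference trainer: explicit loops over cells using the scalar
    neighborhood function; shares only the documented RNG protocol with
    the implementation."""
    from gumatrix.lattice import _wrapped_delta

    n, d = data.shape
    rng = np.random.default_rng(seed)
    weights = data[rng.integers(0, n, size=lattice.n_units)].reshape(
        lattice.lines, lattice.columns, d
    ).copy()
    means = {cell: data[idx].mean(axis=0) for cell, idx in assignment.cell_members.items()}

    def reset():
        for (line, column), mean in means.items():
            weights[line - 1, column - 1] = mean

    reset()
    for radius in cooling_schedule(lattice):
        for i in rng.permutation(n):
            x = data[i]
            # exhaustive BMU scan
            best, best_d = None, np.inf
            for line in range(1, lattice.lines + 1):
                for column in range(1, lattice.columns + 1):
                    dist = float(np.sum((weights[line - 1, column - 1] - x) ** 2))
                    if dist < best_d:
                        best, best_d = (line, column), dist
            # scalar neighborhood update
            for line in range(1, lattice.lines + 1):
                for column in range(1, lattice.columns + 1):
                    dl = _wrapped_delta(best[0], line, lattice.lines)
                    dc = _wrapped_delta(best[1], column, lattice.columns)
                    q = (dl * dl + dc * dc) / (math.pi * radius * radius)
                    if q < 1.0:
                        w = weights[line - 1, column - 1]
                        weights[line - 1, column - 1] = w + (1.0 - q) * (x - w)
            weights[best[0] - 1, best[1] - 1] = x
        reset()
    return weights


class TestTrainSesom:
    def _assignment(self, proj, lattice):
        return map_projection_to_grid(proj, lattice)

    def test_matches_naive_reference(self, rng):
        lattice = Lattice(6, 8)
        data = rng.normal(size=(12, 3))
        proj = rng.normal(size=(12, 2))
        asg = self._assignment(proj, lattice)
        got = train_sesom(data, asg, lattice, TrainingConfig(seed=11))
        expected = _reference_train(data, asg, lattice, seed=11)
        np.testing.assert_allclose(got.weights, expected, rtol=1e-10, atol=1e-12)

    def test_deterministic_under_fixed_seed(self, tiny_mixture):
        ds, proj = tiny_mixture
        lattice = Lattice(9, 9)
        asg = self._assignment(proj, lattice)
        a = train_sesom(ds.data, asg, lattice, TrainingConfig(seed=3))
        b = train_sesom(ds.data, asg, lattice, TrainingConfig(seed=3))
        assert np.array_equal(a.weights, b.weights)

    def test_reset_postcondition_exact(self, tiny_mixture):
        """Predefined cells end exactly at the mean of their data points."""
        ds, proj = tiny_mixture
        lattice = Lattice(12, 12)
        asg = self._assignment(proj, lattice)
        grid = train_sesom(ds.data, asg, lattice, TrainingConfig(seed=5))
        for cell, idx in asg.cell_members.items():
            np.testing.assert_array_equal(
                grid.weights[cell.line - 1, cell.column - 1],
                ds.data[idx].mean(axis=0),
            )

    def test_identical_points_collapse_predefined_cells(self):
        lattice = Lattice(5, 5)
        v = np.array([2.0, -1.0, 0.5])
        data = np.tile(v, (8, 1))
        proj = np.random.default_rng(1).normal(size=(8, 2))
        asg = self._assignment(proj, lattice)
        grid = train_sesom(data, asg, lattice, TrainingConfig(seed=0))
        for cell in asg.cell_members:
            np.testing.assert_array_equal(grid.weights[cell.line - 1, cell.column - 1], v)

    def test_single_point_fills_its_map(self):
        """n=1: prototypes are initialized from the data (the single
        point) and every update pulls toward it, so the whole map equals
        the point and its cell holds it exactly."""
        lattice = Lattice(20, 20)
        v = np.array([1.5, -2.0, 0.25])
        asg = self._assignment(np.array([[0.3, 0.7]]), lattice)
        grid = train_sesom(v[None, :], asg, lattice, TrainingConfig(seed=4))
        cell = asg.position_of(0)
        np.testing.assert_array_equal(grid.weights[cell.line - 1, cell.column - 1], v)
        np.testing.assert_array_equal(grid.weights, np.broadcast_to(v, (20, 20, 3)))

    def test_output_dimensionality_matches_input(self, tiny_mixture):
        ds, proj = tiny_mixture
        lattice = Lattice(9, 9)
        grid = train_sesom(ds.data, self._assignment(proj, lattice), lattice)
        assert grid.weights.shape == (9, 9, ds.data.shape[1])
        assert np.all(np.isfinite(grid.weights))

    def test_empty_data_rejected(self):
        lattice = Lattice(3, 3)
        proj = np.array([[0.0, 0.0], [1.0, 1.0]])
        asg = self._assignment(proj, lattice)
        with pytest.raises(ValueError):
            train_sesom(np.zeros((0, 3)), asg, lattice)

    def test_mismatched_assignment_rejected(self, rng):
        lattice = Lattice(3, 3)
        asg = self._assignment(rng.normal(size=(5, 2)), lattice)
        with pytest.raises(ValueError):
            train_sesom(rng.normal(size=(6, 2)), asg, lattice)
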