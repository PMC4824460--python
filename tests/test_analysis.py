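"""Orientation histograms, L2 metric, persistence, vorticity, fronts."""

import numpy as np
import pytest

from micropotts.analysis import (Trajectory, axis_mode, fold_axis,
                                 front_displacement, l2_distance,
                                 orientation_histogram, persistence_stats,
                                 vorticity_field)


class TestOrientationHistogram:
    def test_single_angle_single_bin(self):
        h = orientation_histogram([45.0] * 20)
        assert h.probabilities.max() == 1.0
        assert h.probabilities.sum() == pytest.approx(1.0)

    def test_axes_are_undirected(self):
        assert fold_axis(np.array([135.0]))[0] == pytest.approx(-45.0)
        assert fold_axis(np.array([-90.0]))[0] == pytest.approx(90.0)
        h1 = orientation_histogram([135.0, 30.0])
        h2 = orientation_histogram([-45.0, 210.0])
        assert np.array_equal(h1.probabilities, h2.probabilities)

    def test_uniform_angles_fill_bins_evenly(self):
        rng = np.random.default_rng(0)
        h = orientation_histogram(rng.uniform(-90, 90, 10000))
        mean_p = h.probabilities.mean()
        assert h.probabilities.max() <= 2 * mean_p

    def test_normalization_and_bin_width(self):
        h = orientation_histogram(np.linspace(-89, 89, 50))
        assert h.probabilities.sum() == pytest.approx(1.0)
        assert np.diff(h.bin_edges) == pytest.approx(6.0)

    def test_axis_mode_on_cardinal_peak(self):
        rng = np.random.default_rng(1)
        angles = 90.0 + rng.normal(0, 4, 500)  # peak at the fold point
        assert axis_mode(angles) == pytest.approx(90.0)


class TestL2Distance:
    def test_identical_histograms(self):
        p = np.array([0.2, 0.3, 0.5])
        assert l2_distance(p, p) == 0.0

    def test_doubled_histogram_gives_bin_count(self):
        p = np.full(12, 1.0 / 12)
        assert l2_distance(p, 2 * p) == pytest.approx(12.0)

    def test_worked_example(self):
        assert l2_distance(np.array([0.5, 0.5]),
                           np.array([0.6, 0.4])) == pytest.approx(0.08)

    def test_zero_reference_bins_excluded(self):
        assert l2_distance(np.array([0.5, 0.0, 0.5]),
                           np.array([0.4, 0.2, 0.4])) == pytest.approx(
            0.01 / 0.25 + 0.01 / 0.25)

    def test_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.dirichlet(np.ones(30))
            q = rng.dirichlet(np.ones(30))
            assert l2_distance(p, q) >= 0


class TestPersistence:
    def test_straight_trajectory_reports_cap(self):
        t = np.arange(5000)
        pos = np.stack([0.01 * t, 0.005 * t], axis=1)
        speed, tau, lp = persistence_stats(Trajectory(pos), stride=100,
                                           cap=1e6)
        assert tau == 1e6

    def test_recovers_known_decorrelation_time(self):
        # headings with exponential angular decorrelation, tau = 500 steps
        rng = np.random.default_rng(3)
        n = 100000
        tau_steps = 500.0
        sigma = np.sqrt(2.0 / tau_steps)
        theta = np.cumsum(rng.normal(0, sigma, n))
        pos = np.zeros((n, 2))
        pos[1:, 0] = np.cumsum(np.cos(theta[:-1]))
        pos[1:, 1] = np.cumsum(np.sin(theta[:-1]))
        _, tau, _ = persistence_stats(Trajectory(pos), stride=1, max_lag=200)
        assert tau == pytest.approx(tau_steps, rel=0.10)

    def test_random_walk_decorrelates_immediately(self):
        rng = np.random.default_rng(4)
        pos = np.cumsum(rng.normal(0, 1, (20000, 2)), axis=0)
        _, tau, _ = persistence_stats(Trajectory(pos), stride=1)
        assert tau < 2.0

    def test_immobile_cell_flagged(self):
        with pytest.raises(ValueError, match="immobile"):
            persistence_stats(Trajectory(np.zeros((5000, 2))), stride=100)

    def test_length_equals_time_times_speed(self):
        rng = np.random.default_rng(5)
        theta = np.cumsum(rng.normal(0, 0.05, 30000))
        pos = np.zeros((30000, 2))
        pos[1:, 0] = np.cumsum(np.cos(theta[:-1]))
        pos[1:, 1] = np.cumsum(np.sin(theta[:-1]))
        speed, tau, lp = persistence_stats(Trajectory(pos), stride=10)
        assert lp == pytest.approx(speed * tau, rel=1e-9)


def synthetic_cells(n_side, spacing, velocity_fn):
    """Tile cells on a grid; return (grid, areas, centers, velocities)."""
    n = n_side * n_side
    size = n_side * spacing
    grid = np.zeros((size, size), np.int32)
    areas = np.zeros(n + 1)
    centers = np.zeros((n + 1, 2))
    vels = np.zeros((n + 1, 2))
    cid = 0
    for i in range(n_side):
        for j in range(n_side):
            cid += 1
            grid[i * spacing:(i + 1) * spacing,
                 j * spacing:(j + 1) * spacing] = cid
            c = np.array([(i + 0.5) * spacing, (j + 0.5) * spacing])
            centers[cid] = c
            areas[cid] = spacing ** 2
            vels[cid] = velocity_fn(c - size / 2)
    return grid, areas, centers, vels


class TestVorticity:
    def test_counterclockwise_rotation_is_positive(self):
        omega0 = 0.01
        grid, areas, centers, vels = synthetic_cells(
            9, 10, lambda r: omega0 * np.array([-r[1], r[0]]))
        w = vorticity_field(grid, areas, centers, vels, beta=1.0)
        core = w[30:60, 30:60]
        assert (core > 0).all()

    def test_uniform_translation_is_curl_free(self):
        # evaluated where the neighborhood is symmetric (cell-center sites),
        # a pure translation contributes exactly no vorticity
        # odd spacing puts every cell center exactly on a site center
        grid, areas, centers, vels = synthetic_cells(
            9, 11, lambda r: np.array([0.02, 0.01]))
        w = vorticity_field(grid, areas, centers, vels, beta=1.0)
        grid2, areas2, centers2, vels2 = synthetic_cells(
            9, 11, lambda r: 0.01 * np.array([-r[1], r[0]]))
        w_rot = vorticity_field(grid2, areas2, centers2, vels2, beta=1.0)
        core_centers = [(int(c[0]), int(c[1]))
                        for c in centers[1:] if 33 <= c[0] <= 66
                        and 33 <= c[1] <= 66]
        w_t = np.array([w[i, j] for i, j in core_centers])
        w_r = np.array([w_rot[i, j] for i, j in core_centers])
        assert np.abs(w_t).max() < 1e-6 * np.abs(w_r).max()

    def test_single_cell_matches_hand_computation(self):
        grid = np.zeros((20, 20), np.int32)
        grid[5:15, 5:15] = 1
        areas = np.array([0.0, 100.0])
        centers = np.array([[0.0, 0.0], [10.0, 10.0]])
        vels = np.array([[0.0, 0.0], [0.3, -0.2]])
        w = vorticity_field(grid, areas, centers, vels, beta=1.0)
        # at site (7, 12): r = center - site center = (2.5, -2.5)
        expect = (vels[1, 1] * 2.5 - vels[1, 0] * (-2.5)) / 100.0
        assert w[7, 12] == pytest.approx(expect)

    def test_zero_outside_cells(self):
        grid = np.zeros((10, 10), np.int32)
        w = vorticity_field(grid, np.zeros(1), np.zeros((1, 2)),
                            np.zeros((1, 2)), beta=1.0)
        assert (w == 0).all()


class TestFrontDisplacement:
    def test_static_configuration(self):
        fronts = np.full((10, 3), 25.0)
        disp, vel = front_displacement(fronts, barrier_front_um=20.0)
        assert (disp == 5.0).all()
        assert vel == pytest.approx(np.zeros(10), abs=1e-12)

    def test_steady_advance(self):
        fronts = 20.0 + np.arange(30)[:, None] * np.ones((1, 2))
        disp, vel = front_displacement(fronts, barrier_front_um=20.0,
                                       smooth=1)
        assert np.diff(disp) == pytest.approx(1.0)
        assert vel[5:-5] == pytest.approx(1.0)
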