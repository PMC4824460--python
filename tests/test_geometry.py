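"""Circle/ellipse fitting, contour normals and free-arc detection."""

import numpy as np
import pytest

import micropotts as mp
from micropotts.geometry import (detect_free_arcs, estimate_normal,
                                 fit_circle_arc, fit_ellipse)


class TestCircleFit:
    def test_exact_circle(self):
        t = np.linspace(0, 1.5 * np.pi, 40)
        pts = np.stack([3 + 20 * np.cos(t), -2 + 20 * np.sin(t)], axis=1)
        (cx, cy), r = fit_circle_arc(pts)
        assert r == pytest.approx(20.0, abs=1e-6)
        assert (cx, cy) == pytest.approx((3.0, -2.0), abs=1e-6)

    def test_noisy_semicircle_radius_recovery(self):
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(100):
            t = rng.uniform(0, np.pi, 60)
            pts = np.stack([20 * np.cos(t), 20 * np.sin(t)], axis=1)
            pts += rng.normal(0, 0.2, pts.shape)
            _, r = fit_circle_arc(pts)
            errs.append(abs(r - 20.0) / 20.0)
        assert np.mean(errs) < 0.02

    def test_endpoint_weighting_pins_the_circle(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, np.pi, 50)
        pts = np.stack([15 * np.cos(t), 15 * np.sin(t)], axis=1)
        pts[1:-1] += rng.normal(0, 0.5, (48, 2))
        ends = pts[[0, -1]]
        (cx, cy), r = fit_circle_arc(pts, endpoints=ends)
        for e in ends:
            gap = abs(np.hypot(e[0] - cx, e[1] - cy) - r)
            assert gap < 0.5  # within half a site of both endpoints

    def test_collinear_points_flagged_straight(self):
        pts = np.stack([np.arange(10.0), 2 * np.arange(10.0)], axis=1)
        _, r = fit_circle_arc(pts)
        assert np.isinf(r)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, np.pi, 30)
        pts = np.stack([12 * np.cos(t), 12 * np.sin(t)], axis=1)
        pts += rng.normal(0, 0.1, pts.shape)
        _, r0 = fit_circle_arc(pts)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        _, r1 = fit_circle_arc(pts @ R.T + np.array([5.0, -11.0]))
        assert r1 == pytest.approx(r0, rel=1e-9)


class TestEllipseFit:
    @staticmethod
    def rect_sites(w, h, angle_deg=0.0):
        xs, ys = np.mgrid[0:w, 0:h]
        pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
        pts -= pts.mean(axis=0)
        a = np.radians(angle_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return np.round(pts @ R.T).astype(int)

    def test_axis_aligned_rectangle(self):
        fit = fit_ellipse(self.rect_sites(40, 10))
        assert fit.orientation == pytest.approx(0.0, abs=1.0)
        assert fit.major_axis / fit.minor_axis == pytest.approx(4.0, rel=0.05)

    def test_rotated_rectangle(self):
        fit = fit_ellipse(self.rect_sites(40, 10, angle_deg=30.0))
        assert fit.orientation == pytest.approx(30.0, abs=2.0)

    def test_disc_is_degenerate(self, disc56):
        grid, _, _ = disc56
        fit = fit_ellipse(np.argwhere(grid))
        assert fit.degenerate

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.zeros((4, 2)))

    def test_orientation_equivariance_mod_180(self):
        base = self.rect_sites(36, 12, angle_deg=0.0)
        for rot in (50.0, 120.0):
            fit = fit_ellipse(self.rect_sites(36, 12, angle_deg=rot))
            expect = ((rot + 90.0) % 180.0) - 90.0
            assert fit.orientation == pytest.approx(expect, abs=2.5)


class TestNormals:
    def test_half_plane_edge(self):
        grid = np.zeros((40, 40), np.int32)
        grid[:20, :] = 1  # vertical cell edge at x = 20
        n = estimate_normal(grid, 1, (19, 20))
        assert n == pytest.approx([1.0, 0.0], abs=1e-9)

    def test_disc_radial_error_small(self, disc56):
        grid, center, R = disc56
        g = grid.astype(np.int32)
        inner = g[1:-1, 1:-1] == 1
        nb_out = ((g[:-2, 1:-1] != 1) | (g[2:, 1:-1] != 1)
                  | (g[1:-1, :-2] != 1) | (g[1:-1, 2:] != 1))
        bnd = np.argwhere(inner & nb_out) + 1
        errs = []
        for x, y in bnd:
            n = estimate_normal(g, 1, (x, y))
            radial = np.array([x + 0.5 - center, y + 0.5 - center])
            radial /= np.hypot(*radial)
            errs.append(np.arccos(np.clip(n @ radial, -1, 1)))
        mae_frac = np.mean(errs) / (2 * np.pi)
        assert mae_frac <= 0.012  # at most the published 1.2% of a full angle

    def test_square_corner_bisector(self):
        grid = np.zeros((40, 40), np.int32)
        grid[5:20, 5:20] = 1
        n = estimate_normal(grid, 1, (19, 19))
        ang = np.degrees(np.arctan2(n[1], n[0]))
        assert ang == pytest.approx(45.0, abs=5.0)

    def test_isolated_site_falls_back_to_com_direction(self):
        grid = np.zeros((60, 60), np.int32)
        grid[10:20, 10:20] = 1
        grid[40, 40] = 1  # stray far site of the same cell
        n = estimate_normal(grid, 1, (40, 40), mask_radius=1)
        # only itself in the tiny mask -> centroid == center -> COM fallback
        assert n @ np.array([1.0, 1.0]) > 0


class TestArcs:
    def spread_state(self, pattern, dims=None, seed=7, sweeps=800):
        params = mp.get_preset("generic", beta=0.5)
        mask = mp.make_pattern(mp.PatternSpec(pattern, dims=dims or {},
                                              beta=0.5))
        sim = mp.Simulation(params, mask, seed=seed)
        cid = sim.seed_cell()
        sim.spread(sweeps)
        return sim.state, cid

    def test_fully_adhesive_cell_has_no_arcs(self):
        params = mp.get_preset("generic", beta=1.0)
        mask = mp.make_pattern(mp.PatternSpec("uniform", dims={"width": 60},
                                              beta=1.0))
        sim = mp.Simulation(params, mask, seed=3)
        cid = sim.seed_cell()
        sim.spread(300)
        assert detect_free_arcs(sim.state, cid) == []

    def test_two_stripe_fixture_gives_two_arcs(self):
        # cell spanning two parallel stripes: one arc per gap side
        beta = 1.0
        params = mp.get_preset("generic", beta=beta)
        grid = np.zeros((60, 60), bool)
        grid[:, 20:26] = True
        grid[:, 34:40] = True
        mask = mp.AdhesiveMask(grid, beta)
        st = mp.LatticeState(mask, params)
        st.grid[20:40, 22:38] = 1   # rectangle bridging the gap
        st.n_ids = 1
        st._init_cell_defaults(1)
        st.remeasure(1)
        arcs = detect_free_arcs(st, 1)
        assert len(arcs) == 2
        for a in arcs:
            # chord spans the 8-um non-adhesive gap between the stripes
            assert a.chord == pytest.approx(8.0, abs=2.5)

    def test_contour_length_at_least_chord(self):
        st, cid = self.spread_state("X")
        arcs = detect_free_arcs(st, cid)
        assert arcs, "expected free arcs over the concave gaps"
        for a in arcs:
            assert a.contour_length >= a.chord
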