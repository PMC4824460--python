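"""Metropolis dynamics, polarity, proliferation and mitosis."""

import numpy as np
import pytest

import micropotts as mp
from micropotts import kernel as K
from micropotts.dynamics import division_rate, update_polarity


class TestPolarity:
    def test_fixed_point(self):
        p = np.array([0.3, -0.1])
        assert update_polarity(p, p, 10.0) == pytest.approx(p)

    def test_closed_form_with_constant_velocity(self):
        tau = 10.0
        v = np.array([0.5, 0.0])
        p = np.zeros(2)
        for t in range(1, 40):
            p = update_polarity(p, v, tau)
            expect = v * (1 - (1 - 1 / tau) ** t)
            assert p == pytest.approx(expect, rel=1e-12)
        assert p == pytest.approx(v, rel=0.02)

    def test_geometric_decay_without_motion(self):
        tau = 8.0
        p = np.array([1.0, 0.0])
        for _ in range(5):
            p_next = update_polarity(p, np.zeros(2), tau)
            assert np.hypot(*p_next) == pytest.approx(
                np.hypot(*p) * (1 - 1 / tau))
            p = p_next

    def test_tau_below_one_rejected(self):
        with pytest.raises(ValueError):
            update_polarity(np.zeros(2), np.ones(2), 0.5)


class TestDivisionRate:
    def test_hill_midpoint(self):
        p = mp.get_preset("HaCaT")
        assert division_rate(p.A0, p) == pytest.approx(p.r0 / 2)

    def test_zero_area(self):
        assert division_rate(0.0, mp.get_preset("HaCaT")) == 0.0

    def test_published_value_at_twice_target_size(self):
        p = mp.get_preset("HaCaT")  # r0 = 8e-4 per MCS, m = 4
        assert division_rate(2 * p.A0, p) == pytest.approx(
            0.0008 * 16 / 17, rel=1e-12)


class TestMetropolis:
    def test_identical_seeds_give_identical_trajectories(self):
        def run():
            params = mp.get_preset("generic", beta=0.5)
            mask = mp.make_pattern(mp.PatternSpec("L", beta=0.5))
            sim = mp.Simulation(params, mask, seed=77)
            sim.seed_cell()
            sim.spread(300)
            return sim.state.grid.copy()

        assert np.array_equal(run(), run())

    def test_zero_temperature_dynamics_never_raises_energy(self):
        # at T -> 0 only dH < 0 moves are accepted: H decreases monotonically
        params = mp.get_preset("generic", beta=1.0).with_updates(
            T=1e-9, mu=0.0)
        mask = mp.make_pattern(mp.PatternSpec("uniform", dims={"width": 50},
                                              beta=1.0))
        sim = mp.Simulation(params, mask, seed=5)
        st = sim.state
        st.grid[15:35, 20:30] = 1   # elongated cell, relaxes downhill
        st.n_ids = 1
        st._init_cell_defaults(1)
        st.remeasure(1)
        H = mp.total_energy(st).total
        for _ in range(6):
            sim.run(20)
            H_next = mp.total_energy(st).total
            assert H_next <= H + 1e-9
            H = H_next

    def test_relaxation_to_near_circular_shape(self):
        params = mp.get_preset("generic", beta=0.5)
        mask = mp.make_pattern(mp.PatternSpec("uniform", dims={"width": 70},
                                              beta=0.5))
        sim = mp.Simulation(params, mask, seed=8)
        st = sim.state
        st.grid[30:110, 55:85] = 1  # strongly elongated initial cell
        st.n_ids = 1
        st._init_cell_defaults(1)
        st.remeasure(1)
        sim.spread(2000)
        a, p = st.measure_geometry(1)
        assert 4 * np.pi * a / p ** 2 >= 0.9


class TestSpreading:
    def test_generic_cell_covers_the_L_pattern(self):
        params = mp.get_preset("generic", beta=0.5)
        mask = mp.make_pattern(mp.PatternSpec("L", beta=0.5))
        sim = mp.Simulation(params, mask, seed=11)
        cid = sim.seed_cell()
        sim.spread(3000)
        coverage = sim.state.ci[K.NADH, cid] / mask.grid.sum()
        assert coverage >= 0.9


class TestMitosis:
    def test_preshaped_rectangle_divides_along_its_long_axis(self):
        hits = 0
        n = 12
        for s in range(n):
            params = mp.get_preset("generic", beta=0.5)
            mask = mp.make_pattern(mp.PatternSpec(
                "uniform", dims={"width": 60}, beta=0.5))
            sim = mp.Simulation(params, mask, seed=200 + s)
            st = sim.state
            st.grid[50:70, 20:100] = 1  # 4:1 rectangle along y
            st.n_ids = 1
            st._init_cell_defaults(1)
            st.remeasure(1)
            ang, _ = sim.divide_cell(1)
            if abs(abs(ang) - 90.0) <= 6.0:
                hits += 1
        assert hits >= int(0.9 * n)

    def test_daughters_partition_parent(self):
        params = mp.get_preset("generic", beta=0.5)
        mask = mp.make_pattern(mp.PatternSpec("bar", beta=0.5))
        sim = mp.Simulation(params, mask, seed=4)
        cid = sim.seed_cell()
        sim.spread(800)
        parent_sites = {tuple(s) for s in sim.state.sites_of(cid)}
        A_parent = sim.state.area_um2(cid)
        ang, (d1, d2) = sim.divide_cell(cid)
        s1 = {tuple(s) for s in sim.state.sites_of(d1)}
        s2 = {tuple(s) for s in sim.state.sites_of(d2)}
        assert not s1 & s2
        a1 = sim.state.area_um2(d1)
        a2 = sim.state.area_um2(d2)
        total = a1 + a2
        assert 0.4 <= a1 / total <= 0.6
        # parent contracted to ~0.36 A_b before the split
        assert total == pytest.approx(0.36 * A_parent, rel=0.1)
        # daughters are 4-connected
        from scipy import ndimage
        struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for d in (d1, d2):
            _, ncomp = ndimage.label(sim.state.grid == d, structure=struct)
            assert ncomp == 1

    def test_mitotic_parameter_overrides_and_restoration(self):
        params = mp.get_preset("generic", beta=0.5)
        mask = mp.make_pattern(mp.PatternSpec("bar", beta=0.5))
        sim = mp.Simulation(params, mask, seed=6)
        cid = sim.seed_cell()
        sim.spread(400)
        A_b = sim.state.area_um2(cid)
        ang, (d1, d2) = sim.divide_cell(cid)
        rec = sim.division_log[-1]
        assert rec["A_b"] == pytest.approx(A_b)
        # both daughters back to interphase parameters
        for d in (d1, d2):
            assert sim.state.cf[K.SIG, d] == params.sigma
            assert sim.state.cf[K.KK, d] == params.k
            assert sim.state.ci[K.PHASE, d] == 0
            assert (sim.state.cf[K.PX, d], sim.state.cf[K.PY, d]) == (0, 0)


class TestSpeedPersistenceCoupling:
    def test_persistence_time_increases_with_migratory_strength(self):
        from micropotts.analysis import Trajectory, persistence_stats

        # three strengths on the rising branch (persistence saturates and can
        # even destabilize at yet higher speeds, as reported)
        taus = []
        for mu in (0.05, 0.10, 0.19):
            params = mp.get_preset("MCF10A").with_updates(mu=mu)
            mask = mp.make_pattern(mp.PatternSpec(
                "uniform", dims={"width": 120.0}, beta=params.beta))
            sim = mp.Simulation(params, mask, seed=55)
            pos = sim.free_migration_trajectory(15000, relax_mcs=1500)
            try:
                _, tau_p, _ = persistence_stats(Trajectory(pos), stride=100)
            except ValueError:
                tau_p = 0.0
            taus.append(tau_p)
        assert taus[0] < taus[1] < taus[2]
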