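"""Hamiltonian terms: closed forms, junction bookkeeping, migration bias."""

import numpy as np
import pytest

import micropotts as mp
from micropotts import kernel as K
from micropotts.energy import contact_delta, migration_delta, total_energy
from micropotts.params import adhesion_reference_area


def uniform_state(params, width_um=60.0):
    mask = mp.make_pattern(mp.PatternSpec("uniform",
                                          dims={"width": width_um},
                                          beta=params.beta))
    return mp.LatticeState(mask, params)


class TestAdhesionReferenceArea:
    def test_w_equals_four_sigma(self):
        assert adhesion_reference_area(4.0, 1.0, 1300.0) == pytest.approx(1300.0)

    def test_generic_cell_value(self):
        # solve W * A_ref^2 / (A_ref + A0)^2 = sigma numerically as the oracle
        from scipy.optimize import brentq

        W, sigma, A0 = 20.0, 1.0, 1300.0
        oracle = brentq(lambda a: W * a * a / (a + A0) ** 2 - sigma, 1.0, 1e5)
        assert adhesion_reference_area(W, sigma, A0) == pytest.approx(oracle,
                                                                      rel=1e-9)
        assert adhesion_reference_area(W, sigma, A0) == pytest.approx(374.2,
                                                                      abs=0.3)

    def test_w_below_sigma_rejected(self):
        with pytest.raises(ValueError, match="spreading"):
            adhesion_reference_area(0.5, 1.0, 1000.0)

    def test_divergence_as_w_approaches_sigma(self):
        assert adhesion_reference_area(1.0 + 1e-9, 1.0, 1000.0) > 1e9


class TestTotalEnergy:
    def test_circular_cell_closed_form(self):
        params = mp.get_preset("generic", beta=0.5)
        st = uniform_state(params)
        R = 12.0
        st.rasterize_disc((30.0, 30.0), R)
        br = total_energy(st)
        area = np.pi * R * R
        assert br.surface == pytest.approx(params.sigma * area, rel=0.01)
        # midpoint marching squares overestimates a smooth perimeter by ~6%
        assert br.line == pytest.approx(params.lambda_s * 2 * np.pi * R,
                                        rel=0.08)
        assert br.adhesion == pytest.approx(
            -params.E0 * area / (params.A_ref + area), rel=0.01)
        assert br.arcs == 0.0 and br.contact == 0.0
        assert br.total == pytest.approx(br.surface + br.line + br.adhesion)

    def test_adhesion_saturation_midpoint(self):
        params = mp.get_preset("generic", beta=0.5)
        st = uniform_state(params)
        R = np.sqrt(params.A_ref / np.pi)
        st.rasterize_disc((30.0, 30.0), R)
        br = total_energy(st)
        assert br.adhesion == pytest.approx(-params.E0 / 2, rel=0.02)
        assert -params.E0 < br.adhesion <= 0.0


class TestAdhesionTermShape:
    def test_monotone_increasing_and_bounded(self):
        p = mp.get_preset("generic")
        a_ad = np.linspace(0, 20 * p.A0, 400)
        term = -p.E0 * a_ad / (p.A_ref + a_ad)
        assert (np.diff(term) < 0).all()      # more adhesion lowers energy
        assert (term > -p.E0).all() and term[0] == 0.0


class TestCadherinGapSpanning:
    def test_cadherins_extend_pair_over_nonadhesive_gap(self):
        """With the junction tension at the cell-medium level, a pair on H
        spans the gap only with an explicit cadherin energy."""
        def gap_occupancy(c_val):
            params = mp.get_preset("MCF10A", beta=0.5).with_updates(
                c=c_val, mu=0.0)
            mask = mp.make_pattern(mp.PatternSpec("H", dims={"width": 36.0},
                                                  beta=0.5))
            sim = mp.Simulation(params, mask, seed=13)
            st = sim.state
            pts = np.argwhere(st.mask > 0)
            c = pts.mean(axis=0)
            b = st.beta
            st.rasterize_disc(((c[0] + 0.5) * b - 10, (c[1] + 0.5) * b), 8.0)
            st.rasterize_disc(((c[0] + 0.5) * b + 10, (c[1] + 0.5) * b), 8.0)
            sim.spread(2500)
            return ((st.grid > 0) & (st.mask == 0)).sum()

        assert gap_occupancy(-6.3) > 1.1 * gap_occupancy(0.0)


class TestJunctionBookkeeping:
    """Frozen lattice fixtures for the three unit-edge junction cases."""

    def params(self):
        return mp.get_preset("generic")  # lambda_s 10, lambda_cc 5, c -10

    def test_extension_without_contact(self):
        p = self.params()
        g = np.zeros((10, 10), np.int32)
        g[4:6, 4:6] = 1
        # site above the block: one cell neighbor, three medium neighbors
        dE = contact_delta(g, (4, 6), 1, p)
        assert dE == pytest.approx(2 * p.lambda_s)

    def test_extension_forming_new_contact_at_terminus(self):
        p = self.params()
        g = np.zeros((10, 10), np.int32)
        g[2, 2:4] = 1          # cell A column
        g[3, 2:5] = 2          # cell B column, one site taller
        # A extends beyond the junction terminus: new adherens junction zips
        dE = contact_delta(g, (2, 4), 1, p)
        assert dE == pytest.approx(p.lambda_s + 2 * p.lambda_cc + p.c)

    def test_extension_of_existing_contact_is_deformation(self):
        p = self.params()
        g = np.zeros((10, 10), np.int32)
        for s in ((2, 2), (2, 1), (1, 1), (0, 1), (0, 2), (0, 3), (0, 4),
                  (1, 4)):
            g[s] = 1           # cell A hooks around
        for s in ((3, 2), (3, 3), (3, 4), (2, 4)):
            g[s] = 2           # cell B
        # filling (2, 3) bridges two junction stretches: pure deformation
        dE = contact_delta(g, (2, 3), 1, p)
        assert dE == pytest.approx(4 * p.lambda_cc)
        assert dE == pytest.approx(2 * p.lambda_s)  # with lambda_cc = lambda_s/2


class TestMigrationBias:
    def polarized_state(self):
        params = mp.get_preset("generic", beta=0.5).with_updates(mu=2.0)
        st = uniform_state(params, width_um=40.0)
        st.grid[20:31, 20:31] = 1   # COM at lattice point (25.5, 25.5)
        st.n_ids = 1
        st._init_cell_defaults(1)
        st.remeasure(1)
        st.cf[K.PX, 1] = 1.0
        st.cf[K.PY, 1] = 0.0
        return st, params

    def test_protrusion_at_front(self):
        st, p = self.polarized_state()
        # site straight ahead of the COM along the polarity direction
        prop = mp.FlipProposal(site=(31, 25), from_id=0, to_id=1)
        dHm = migration_delta(st, prop)
        assert dHm == pytest.approx(-p.beta ** 2 * p.mu, rel=0.02)

    def test_lateral_flip_is_unbiased(self):
        st, p = self.polarized_state()
        # site straight above the COM: alpha = pi/2, cos = 0 exactly
        prop = mp.FlipProposal(site=(25, 31), from_id=0, to_id=1)
        assert migration_delta(st, prop) == pytest.approx(0.0, abs=1e-9)

    def test_contact_inhibition_of_locomotion(self):
        st, p = self.polarized_state()
        st.grid[31:35, 20:31] = 2   # neighbor in front
        st.n_ids = 2
        st._init_cell_defaults(2)
        st.remeasure(2)
        st.remeasure(1)
        st.cf[K.MU, 2] = 0.0        # isolate cell 1's term
        prop = mp.FlipProposal(site=(31, 25), from_id=2, to_id=1)
        assert migration_delta(st, prop) == pytest.approx(0.0, abs=1e-12)

    def test_rear_retraction_assisted(self):
        st, p = self.polarized_state()
        prop = mp.FlipProposal(site=(20, 25), from_id=1, to_id=0)
        assert migration_delta(st, prop) < 0

    def test_zero_polarity_disables_bias(self):
        st, p = self.polarized_state()
        st.cf[K.PX, 1] = 0.0
        prop = mp.FlipProposal(site=(31, 25), from_id=0, to_id=1)
        assert migration_delta(st, prop) == 0.0


class TestProtrusionDecay:
    def test_exponential_decay_with_gap_distance(self):
        params = mp.get_preset("MCF10A", beta=0.5)
        grid = np.zeros((80, 80), bool)
        grid[:40, :] = True
        mask = mp.AdhesiveMask(grid, 0.5)
        st = mp.LatticeState(mask, params)
        st.grid[20:45, 30:50] = 1
        st.n_ids = 1
        st._init_cell_defaults(1)
        st.remeasure(1)
        st.cf[K.PX, 1] = 1.0
        st.cf[K.PY, 1] = 0.0
        # two protrusion sites at alpha ~ 0, on and off the adhesive half
        com = st.com_um(1)
        on = mp.FlipProposal(site=(45, 40), from_id=0, to_id=1)
        d_um = st.dist[45, 40]
        assert d_um > 0
        dHm = migration_delta(st, on)
        # magnitude reduced by exp(-d/d0) relative to an on-pattern flip
        base = -st.beta ** 2 * params.mu
        r = (45 + 0.5 - com[0] / st.beta, 40 + 0.5 - com[1] / st.beta)
        cosa = r[0] / np.hypot(*r)
        expect = base * abs(cosa) ** params.eta * np.exp(-d_um / params.d0)
        assert dHm == pytest.approx(expect, rel=1e-6)
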