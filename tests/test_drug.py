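"""Drug transport: diffusivity, hindrance, bolus, advection, exchange and
the three-compartment extravascular system."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from oncoflow import build_tissue_mesh, embed_network, generate_network
from oncoflow.drug import (DrugState, bolus_concentration,
                           hindrance_coefficients, lymphatic_solute_rate,
                           step_extravascular, step_intravascular,
                           stokes_einstein_diffusivity,
                           total_hit_concentration,
                           transvascular_solute_rate, vascular_node_volumes)
from oncoflow.fluid import solve_coupled_pressures
from oncoflow.params import FluidParams, LymphParams
from oncoflow.units import BOLTZMANN


class TestStokesEinstein:
    def test_hand_value(self):
        D = stokes_einstein_diffusivity(1e-9, 310.0, 1e-3)
        assert D == pytest.approx(BOLTZMANN * 310 / (3 * np.pi * 1e-3 * 1e-9),
                                  rel=1e-14)

    def test_order_of_magnitude_for_cytotoxic_drug(self):
        # ~1e-4 mm²/s for a 1 nm molecule at body temperature
        D_mm2 = stokes_einstein_diffusivity(1e-9, 310.0, 1e-3) * 1e6
        assert 1e-5 < D_mm2 < 1e-3

    def test_inverse_size_scaling(self):
        assert stokes_einstein_diffusivity(2e-9, 310, 1e-3) * 2 \
            == pytest.approx(stokes_einstein_diffusivity(1e-9, 310, 1e-3),
                             rel=1e-14)


class TestHindrance:
    def test_unhindered_limit(self):
        D = 4.5e-10
        P, sigma = hindrance_coefficients(1e-12, 1.5e-7, 0.06, 5e-6, D)
        assert P == pytest.approx(0.06 * D / 5e-6, rel=1e-3)
        assert sigma == pytest.approx(0.0, abs=1e-3)

    def test_full_steric_exclusion(self):
        P, sigma = hindrance_coefficients(4e-7, 1.5e-7, 0.06, 5e-6, 4.5e-10)
        assert (P, sigma) == (0.0, 1.0)

    def test_correlation_matches_symbolic_oracle(self):
        # direct evaluation of the implemented pore correlation at λ=0.1
        lam = 0.1
        D, gp, h = 4.5e-10, 0.06, 5e-6
        P, sigma = hindrance_coefficients(lam * 2 * 1.5e-7, 1.5e-7, gp, h, D)
        phi = (1 - lam) ** 2
        H = 1 - 2.1044 * lam + 2.089 * lam ** 3 - 0.948 * lam ** 5
        assert P == pytest.approx(gp * phi * H * D / h, rel=1e-12)
        assert sigma == pytest.approx(
            1 - phi * (2 - phi) * (1 - lam ** 2 / 3), rel=1e-12)

    def test_monotone_in_size_ratio(self):
        lams = np.linspace(0.01, 0.9, 20)
        vals = [hindrance_coefficients(la * 2 * 1e-7, 1e-7, 0.06, 5e-6,
                                       4.5e-10) for la in lams]
        P = [v[0] for v in vals]
        s = [v[1] for v in vals]
        assert all(np.diff(P) < 0)
        assert all(np.diff(s) > 0)


class TestBolus:
    def test_exponential_decay_values(self):
        tau = 21600.0
        assert bolus_concentration(100.0, 100.0, 1.0, tau) == 1.0
        assert bolus_concentration(100.0 + tau, 100.0, 1.0, tau) \
            == pytest.approx(np.exp(-1))
        assert bolus_concentration(100.0 + 3 * tau, 100.0, 1.0, tau) \
            == pytest.approx(np.exp(-3))
        assert bolus_concentration(50.0, 100.0, 1.0, tau) == 0.0

    def test_halflife_conversion(self):
        from oncoflow.units import halflife_to_efolding

        tau = halflife_to_efolding(3600.0)
        assert bolus_concentration(3600.0, 0.0, 1.0, tau) \
            == pytest.approx(0.5, rel=1e-12)


@pytest.fixture(scope="module")
def flow_case():
    mesh = build_tissue_mesh(0.0119, 8, 0.0005)
    net = generate_network(4, 60, mesh)
    cm = embed_network(mesh, net)
    st = solve_coupled_pressures(net, mesh, cm, LymphParams(), FluidParams())
    return mesh, net, cm, st


class TestIntravascular:
    def test_no_flow_keeps_concentration(self, flow_case):
        mesh, net, cm, st = flow_case
        import copy

        st0 = copy.copy(st)
        st0.Q_vsc = np.zeros_like(st.Q_vsc)
        st0.Q_trv = np.zeros_like(st.Q_trv)
        st0.meta = {}                   # no transvascular shares either
        c0 = np.full(net.n_nodes, 0.3)
        c0[net.inlets] = 0.3
        c1 = step_intravascular(net, st0, 0.3, c0, 5.0)
        np.testing.assert_allclose(c1, c0, atol=1e-12)

    def test_steady_plug_flow_single_segment(self):
        """Constant inlet on one segment: the steady profile is flat at the
        inlet value and the front arrives on the advective time scale."""
        from types import SimpleNamespace

        from oncoflow.network import ROLE_INLET, ROLE_OUTLET, VascularNetwork

        L, R = 1e-3, 5e-6
        net = VascularNetwork([[0, 0, 0], [L, 0, 0]], [0], [1], R, 5e-6,
                              1e-7, 0.06, roles=[ROLE_INLET, ROLE_OUTLET])
        v = 1e-4                        # m/s
        Q = v * np.pi * R ** 2
        st = SimpleNamespace(Q_vsc=np.array([Q]), Q_trv=np.array([0.0]))
        c = np.zeros(2)
        transit = L / v
        c = step_intravascular(net, st, 1.0, c, 5 * transit)
        np.testing.assert_allclose(c, 1.0, rtol=1e-6)

    def test_solute_flux_bookkeeping(self, flow_case):
        """Vascular solute mass change equals inlet inflow minus outflow."""
        mesh, net, cm, st = flow_case
        state = DrugState.zeros(net.n_nodes, mesh.n_nodes)
        vol = vascular_node_volumes(net)
        free = np.ones(net.n_nodes, dtype=bool)
        free[net.inlets] = False       # inlet nodes are Dirichlet-held
        c = np.zeros(net.n_nodes)
        m0 = (c * vol)[free].sum()
        c = step_intravascular(net, st, 1.0, c, 30.0, state)
        m1 = (c * vol)[free].sum()
        assert m1 - m0 == pytest.approx(state.injected - state.vascular_out,
                                        rel=1e-6, abs=1e-18)

    def test_positivity(self, flow_case):
        mesh, net, cm, st = flow_case
        c = np.zeros(net.n_nodes)
        for _ in range(50):
            c = step_intravascular(net, st, 1.0, c, 60.0)
        assert c.min() >= 0.0


class TestExchangeRates:
    def test_equilibrium_gives_zero(self):
        assert transvascular_solute_rate(0.4, 0.4, 500.0, 500.0, 1e-11,
                                         1e-7, 0.1, 30.0) == 0.0

    def test_pure_diffusive_term(self):
        val = transvascular_solute_rate(1.0, 0.25, 800.0, 200.0, 0.0,
                                        2e-6, 0.1, 30.0)
        assert val == pytest.approx(2e-6 * 30.0 * 0.75, rel=1e-12)

    def test_upwind_switch_reabsorption(self):
        # p_eff < p_int with empty interstitium: convection carries c_f=0
        val = transvascular_solute_rate(1.0, 0.0, 100.0, 400.0, 1e-11,
                                        2e-6, 0.1, 30.0)
        assert val == pytest.approx(2e-6 * 30.0 * 1.0, rel=1e-12)

    def test_lymphatic_sink_sign_and_value(self):
        assert lymphatic_solute_rate(0.0, 0.0, 100.0, 1e-11, 7000.0) == 0.0
        assert lymphatic_solute_rate(1.0, 100.0, 100.0, 1e-11, 7000.0) == 0.0
        val = lymphatic_solute_rate(1.0, 0.0, 100.0, 1e-11, 7000.0, 0.0)
        assert val == pytest.approx(1e-11 * 7000.0 * (-100.0), rel=1e-12)


class TestExtravascular:
    @staticmethod
    def _no_exchange(mesh):
        z = np.zeros(mesh.n_nodes)
        return (z, z, z, z)

    def test_sealed_conservation(self):
        mesh = build_tissue_mesh(0.008, 8, 0.002)
        state = DrugState.zeros(0, mesh.n_nodes)
        rng = np.random.default_rng(3)
        state.c_f = rng.random(mesh.n_nodes)
        m0 = (state.c_f * mesh.node_volumes).sum()
        v = np.zeros((mesh.n_nodes, 3))
        for _ in range(20):
            step_extravascular(mesh, state, v, 4.5e-10,
                               self._no_exchange(mesh), 0, 0, 0, 0,
                               np.ones(mesh.n_nodes), mesh.tumour_mask, 60.0)
        m1 = (state.c_f * mesh.node_volumes).sum()
        assert abs(m1 - m0) / m0 < 1e-8

    def test_well_mixed_matches_ode_oracle(self):
        """Spatially uniform fields follow the stiff 3-compartment ODE."""
        mesh = build_tissue_mesh(0.008, 6, 0.0039)
        tum = np.ones(mesh.n_nodes, dtype=bool)
        k_on, k_off, k_int, d_i, ecm_level = 0.5, 8e-3, 1e-4, 1e-5, 0.7
        state = DrugState.zeros(0, mesh.n_nodes)
        state.c_f = np.full(mesh.n_nodes, 1.0)
        v = np.zeros((mesh.n_nodes, 3))
        T, dt = 1200.0, 2.0
        for _ in range(int(T / dt)):
            step_extravascular(mesh, state, v, 4.5e-10,
                               self._no_exchange(mesh), k_on, k_off, k_int,
                               d_i, np.full(mesh.n_nodes, ecm_level), tum, dt)

        def rhs(t, y):
            cf, cb, ci = y
            return [-k_on * cf + k_off * cb,
                    k_on * cf - (k_off + k_int) * cb,
                    k_int * cb - d_i * ecm_level * ci]

        sol = solve_ivp(rhs, (0, T), [1.0, 0.0, 0.0], method="LSODA",
                        rtol=1e-10, atol=1e-14)
        cf, cb, ci = sol.y[:, -1]
        # the reaction step is integrated exactly; agreement is limited
        # only by the oracle's own tolerance
        assert state.c_f[0] == pytest.approx(cf, rel=1e-6)
        assert state.c_b[0] == pytest.approx(cb, rel=1e-6)
        assert state.c_i[0] == pytest.approx(ci, rel=1e-6)
        # and the fields stay uniform
        assert np.ptp(state.c_b) < 1e-12

    def test_bound_free_fixed_point(self):
        """Constant c_f forcing drives c_b/c_f to k_on/(k_off + k_int)."""
        mesh = build_tissue_mesh(0.008, 6, 0.0039)
        tum = np.ones(mesh.n_nodes, dtype=bool)
        k_on, k_off, k_int = 0.05, 8e-3, 1e-4
        state = DrugState.zeros(0, mesh.n_nodes)
        v = np.zeros((mesh.n_nodes, 3))
        for _ in range(4000):
            state.c_f[:] = 1.0         # clamp the free drug
            step_extravascular(mesh, state, v, 4.5e-10,
                               self._no_exchange(mesh), k_on, k_off, k_int,
                               0.0, np.ones(mesh.n_nodes), tum, 1.0)
        assert state.c_b[0] == pytest.approx(k_on / (k_off + k_int), rel=1e-2)

    def test_ode_oracle_tight_tolerance_small_dt(self):
        """At the biochemical step size the split scheme matches the ODE
        oracle to 1e-6 relative (linear system, short horizon)."""
        mesh = build_tissue_mesh(0.008, 6, 0.0039)
        tum = np.ones(mesh.n_nodes, dtype=bool)
        k_on, k_off, k_int, d_i = 0.02, 8e-3, 1e-4, 1e-5
        state = DrugState.zeros(0, mesh.n_nodes)
        state.c_f = np.full(mesh.n_nodes, 1.0)
        v = np.zeros((mesh.n_nodes, 3))
        T, dt = 40.0, 0.01
        for _ in range(int(T / dt)):
            step_extravascular(mesh, state, v, 4.5e-10,
                               self._no_exchange(mesh), k_on, k_off, k_int,
                               d_i, np.ones(mesh.n_nodes), tum, dt)
        from scipy.linalg import expm

        A = np.array([[-k_on, k_off, 0.0],
                      [k_on, -(k_off + k_int), 0.0],
                      [0.0, k_int, -d_i]])
        cf, cb, ci = expm(A * T) @ np.array([1.0, 0.0, 0.0])
        assert state.c_f[0] == pytest.approx(cf, rel=1e-6)
        assert state.c_b[0] == pytest.approx(cb, rel=1e-6)
        assert state.c_i[0] == pytest.approx(ci, rel=1e-6)


class TestTotalHit:
    def test_definition_and_host_zero(self):
        mesh = build_tissue_mesh(0.008, 6, 0.001)
        state = DrugState.zeros(0, mesh.n_nodes)
        state.c_b = np.where(mesh.tumour_mask, 0.2, 0.0)
        state.c_i = np.where(mesh.tumour_mask, 0.3, 0.0)
        c_h, integral = total_hit_concentration(state, mesh)
        np.testing.assert_allclose(c_h[mesh.tumour_mask], 0.5)
        np.testing.assert_allclose(c_h[~mesh.tumour_mask], 0.0)
        expected = 0.5 * mesh.node_volumes[mesh.tumour_mask].sum()
        assert integral == pytest.approx(expected, rel=1e-12)
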