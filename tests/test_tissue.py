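"""Oxygen/MDE surrogates, ECM dynamics, Gompertz growth and the radial
growth mechanics with its Euler–Lagrange oracle."""

import numpy as np
import pytest
from scipy.integrate import solve_bvp, solve_ivp

from oncoflow import build_tissue_mesh, embed_network, generate_network
from oncoflow.network import VascularNetwork
from oncoflow.params import MDEParams, OxygenParams, TissueParams
from oncoflow.tissue import (MechanicsSolution, ecm_depletion_rate, ecm_step,
                             growth_strain, mde_surrogate, oxygen_surrogate,
                             relative_tumour_volume, solve_mechanics,
                             solve_radial_equilibrium)


class TestOxygen:
    def test_no_perfused_vessels_gives_anoxia(self, desk_mesh, desk_network,
                                              desk_coupling):
        net = desk_network.copy()
        net.perfused[:] = False
        xi, _ = oxygen_surrogate(desk_mesh, net, desk_coupling, OxygenParams())
        np.testing.assert_allclose(xi, 0.0, atol=1e-15)

    def test_normalised_range(self, desk_mesh, desk_network, desk_coupling):
        xi, ref = oxygen_surrogate(desk_mesh, desk_network, desk_coupling,
                                   OxygenParams())
        assert 0.0 <= xi.min() and xi.max() <= 1.0
        assert ref > 0

    def test_decay_with_distance_from_single_vessel(self):
        mesh = build_tissue_mesh(0.0119, 16, 0.0005)
        E = mesh.edge_length
        net = VascularNetwork([[0.1 * E, E / 2, E / 2],
                               [0.9 * E, E / 2, E / 2]],
                              [0], [1], 5e-6, 5e-6, 1e-7, 0.06)
        cm = embed_network(mesh, net)
        xi, _ = oxygen_surrogate(mesh, net, cm, OxygenParams())
        # sample ξ along a line moving away from the vessel axis
        k = mesh.n // 2
        vals = [xi[mesh.node_index(mesh.n // 2, j, k)]
                for j in range(mesh.n // 2, mesh.n + 1)]
        assert all(np.diff(vals) <= 1e-12)


class TestMDE:
    def test_localised_to_tumour_and_tips(self, desk_mesh):
        mu = mde_surrogate(desk_mesh, desk_mesh.tumour_mask, MDEParams())
        assert mu.min() >= 0.0 and mu.max() <= 1.0
        tum_mean = mu[desk_mesh.tumour_mask].mean()
        far = desk_mesh.radii > 4e-3
        assert tum_mean > 10 * mu[far].mean()

    def test_empty_source_gives_zero(self, desk_mesh):
        mu = mde_surrogate(desk_mesh, np.zeros(desk_mesh.n_nodes, dtype=bool),
                           MDEParams())
        np.testing.assert_allclose(mu, 0.0)


class TestECM:
    def test_remodelling_from_zero_matrix(self):
        p = TissueParams()
        eps = ecm_step(np.zeros(4), np.zeros(4), np.full(4, 0.5),
                       np.zeros(4), np.ones(4, dtype=bool), 1e-4, p)
        assert np.all(eps > 0)

    def test_depletion_inactive_below_threshold(self):
        p = TissueParams()
        C = ecm_depletion_rate(np.array([0.5]), np.array([p.ecm_threshold / 2]),
                               np.array([True]), p)
        assert C[0] == 0.0
        # and inactive outside the tumour region
        C = ecm_depletion_rate(np.array([0.5]), np.array([1.0]),
                               np.array([False]), p)
        assert C[0] == 0.0

    def test_depletion_clamps_negative_base(self):
        p = TissueParams(a_d=0.5)
        C = ecm_depletion_rate(np.array([p.ci_threshold / 2]),
                               np.array([1.0]), np.array([True]), p)
        assert C[0] == 0.0

    def test_one_day_integration_matches_ode_oracle(self):
        p = TissueParams()
        xi, mde, ci = 0.6, 0.8, 0.05
        eps0 = 0.4

        def rhs(t, y):
            eps = max(y[0], 0.0)
            C = (p.delta_d * eps * max(ci - p.ci_threshold, 0.0) ** p.a_d
                 if eps > p.ecm_threshold else 0.0)
            return [p.lambda_ecm * xi * np.exp(-2 * eps / p.ecm_scale)
                    - p.delta_ecm * mde * eps - C]

        sol = solve_ivp(rhs, (0, 1.0), [eps0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        ours = ecm_step(np.array([eps0]), np.array([mde]), np.array([xi]),
                        np.array([ci]), np.array([True]), 1.0, p)
        assert ours[0] == pytest.approx(sol.y[0, -1], rel=1e-6)

    def test_drug_strictly_reduces_matrix_rate(self):
        p = TissueParams()
        eps = np.array([0.5])
        args = (np.array([0.8]), np.array([0.6]))
        tum = np.array([True])
        no_drug = ecm_step(eps, *args, np.array([0.0]), tum, 1e-3, p)
        drug = ecm_step(eps, *args, np.array([0.1]), tum, 1e-3, p)
        assert drug[0] < no_drug[0]


class TestGrowthStrain:
    def test_vanishes_without_oxygen_or_matrix(self):
        p = TissueParams()
        th, lam = growth_strain(0.0, 1.0, p)
        assert th == pytest.approx(0.0, abs=1e-15)
        assert lam == pytest.approx(1.0)
        th, _ = growth_strain(0.8, 0.0, p)
        assert th == 0.0

    def test_saturation_limit(self):
        p = TissueParams()
        G = p.alpha_g * 0.5 ** p.delta_g
        th_inf = G * (1.0 - np.exp(-p.beta_g))
        th, _ = growth_strain(1e3, 0.5, p)
        assert th == pytest.approx(th_inf, rel=1e-9)

    def test_stretch_kinematics(self):
        p = TissueParams()
        th, lam = growth_strain(0.7, 0.6, p)
        assert lam == pytest.approx(np.sqrt(2 * th + 1), rel=1e-14)


class TestMechanics:
    def test_no_growth_is_stress_free(self, desk_mesh):
        p = TissueParams()
        sol = solve_mechanics(desk_mesh, np.zeros(desk_mesh.n_nodes),
                              np.ones(desk_mesh.n_nodes), p, 5e-4)
        np.testing.assert_allclose(sol.r, sol.R, rtol=1e-10)
        np.testing.assert_allclose(sol.thp_mid, 0.0, atol=1e-8)

    def test_uniform_free_growth(self):
        # λ_g uniform in an unconstrained body: r = λ_g R, J = λ_g³, no
        # stress
        lam = 1.1
        R = np.linspace(0.0, 1e-2, 60)
        r, E, rel, _ = solve_radial_equilibrium(
            R, np.full(59, lam), np.full(59, 1000.0), 2e4)
        np.testing.assert_allclose(r, lam * R, rtol=1e-12, atol=1e-15)
        assert abs(E) < 1e-10

    def test_equilibrium_residual_is_small(self, desk_mesh):
        p = TissueParams()
        theta = np.where(desk_mesh.tumour_mask, 1.5, 0.0)
        sol = solve_mechanics(desk_mesh, theta, np.ones(desk_mesh.n_nodes),
                              p, 5e-4)
        assert sol.grad_norm < 1e-8

    def test_confined_growth_compresses_tumour(self, desk_mesh):
        p = TissueParams()
        theta = np.where(desk_mesh.tumour_mask, 1.5, 0.0)
        sol = solve_mechanics(desk_mesh, theta, np.ones(desk_mesh.n_nodes),
                              p, 5e-4)
        lam = np.sqrt(2 * 1.5 + 1)
        assert sol.tumour_radius < lam * 5e-4          # confinement
        assert sol.thp_mid[0] < 0.0                    # compressive core

    def test_radial_oracle_euler_lagrange_bvp(self):
        """The energy minimiser must satisfy the Euler–Lagrange two-point
        boundary-value problem of the same stored-energy functional
        (derived symbolically, solved with an independent collocation
        method) to ≤1%."""
        import sympy as sp

        lam_t, m_t, m_h, kappa = 1.6, 800.0, 1200.0, 2.0e4
        a0, R_out = 1.0e-3, 6.0e-3
        wdt = 2.5e-4

        Rs, rs, rps = sp.symbols("R r rp", positive=True)
        lam_s, m_s = sp.symbols("lam m", positive=True)
        x = rps / lam_s
        y = rs / (Rs * lam_s)
        J = x * y ** 2
        I1b = J ** sp.Rational(-2, 3) * (x ** 2 + 2 * y ** 2)
        W = m_s / 2 * (I1b - 3) + kappa / 2 * (J - 1) ** 2
        f = W * lam_s ** 3 * Rs ** 2          # energy density (×4π dR)
        df_drp = sp.diff(f, rps)
        df_dr = sp.diff(f, rs)
        F1 = sp.lambdify((Rs, rs, rps, lam_s, m_s), df_drp, "numpy")
        F0 = sp.lambdify((Rs, rs, rps, lam_s, m_s), df_dr, "numpy")

        def lam_of(R):
            return 1.0 + (lam_t - 1.0) * 0.5 * (1 - np.tanh((R - a0) / wdt))

        def m_of(R):
            return m_h + (m_t - m_h) * 0.5 * (1 - np.tanh((R - a0) / wdt))

        # first-order system for (r, q = ∂f/∂r'): dq/dR = ∂f/∂r
        def ode(R, y):
            r, q = y
            lam = lam_of(R)
            m = m_of(R)
            # invert q = F1(R, r, r') for r' by bisection (monotone in r')
            lo = np.full_like(R, 1e-3)
            hi = np.full_like(R, 6.0)
            for _ in range(70):
                mid = 0.5 * (lo + hi)
                too_low = F1(R, r, mid, lam, m) < q
                lo = np.where(too_low, mid, lo)
                hi = np.where(too_low, hi, mid)
            rp = 0.5 * (lo + hi)
            return np.vstack([rp, F0(R, r, rp, lam, m)])

        def bc(ya, yb):
            # r(R0) = λ_t R0 (regular centre), traction-free outer surface
            return np.array([ya[0] - lam_t * R0, yb[1]])

        R0 = 1e-5
        Rgrid = np.linspace(R0, R_out, 300)
        guess = np.vstack([lam_of(Rgrid) * Rgrid, np.zeros(300)])
        sol = solve_bvp(ode, bc, Rgrid, guess, tol=1e-8, max_nodes=20000)
        assert sol.success

        # package solution on the same smooth profiles
        R = np.linspace(0.0, R_out, 480)
        R_mid = 0.5 * (R[:-1] + R[1:])
        r_pkg, _, rel, _ = solve_radial_equilibrium(
            R, lam_of(R_mid), m_of(R_mid), kappa)
        mask = R >= 5e-5
        r_oracle = sol.sol(R[mask])[0]
        err = np.linalg.norm(r_pkg[mask] - r_oracle) / np.linalg.norm(r_oracle)
        assert err < 0.01


class TestTumourVolume:
    def test_reference_volume_is_zero(self):
        assert relative_tumour_volume(2.5e-9, 2.5e-9) == 0.0

    def test_uniform_stretch_hand_value(self):
        lam = 1.1
        v0 = 4 / 3 * np.pi * (5e-4) ** 3
        assert relative_tumour_volume(v0 * lam ** 3, v0) \
            == pytest.approx(lam ** 3 - 1, rel=1e-12)

    def test_mechanics_volume_matches_deformed_radius(self, desk_mesh):
        p = TissueParams()
        theta = np.where(desk_mesh.tumour_mask, 0.8, 0.0)
        sol = solve_mechanics(desk_mesh, theta, np.ones(desk_mesh.n_nodes),
                              p, 5e-4)
        assert sol.tumour_volume == pytest.approx(
            4 / 3 * np.pi * sol.tumour_radius ** 3, rel=1e-12)
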