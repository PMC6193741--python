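"""Tissue biochemistry and solid biomechanics.

* quasi-steady oxygen surrogate: diffusion from perfused vessels with
  first-order tumour uptake, normalised to [0, 1];
* quasi-steady matrix-degrading-enzyme (MDE) surrogate: diffusion from the
  tumour and active sprout tips with linear decay;
* ECM structural integrity ODE with natural remodelling, MDE degradation
  and cytotoxic-drug depletion;
* modified Gompertz growth strain ϑ_g(ξ, ϵ) and the multiplicative-growth
  modified Neo-Hookean quasi-static mechanics, solved on a reduced radial
  grid (the default scenario is spherically symmetric) by direct energy
  minimisation; tissue hydrostatic pressure THP = κ(J_e − 1) (the deviatoric
  Cauchy stress of the isochoric term is traceless), negative = compressive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .params import MDEParams, OxygenParams, TissueParams


# -- quasi-steady reaction-diffusion surrogates ---------------------------

def _helmholtz_solve(mesh, diffusivity, decay_node, source_node):
    """FV solve of −D∇²u + k·u = s with zero-flux boundaries."""
    from .fluid import _tissue_operator
    L = _tissue_operator(mesh, np.full(mesh.n_nodes, diffusivity))
    V = mesh.node_volumes
    N = mesh.n_nodes
    A = -L + csr_matrix((decay_node * V, (np.arange(N), np.arange(N))),
                        shape=(N, N))
    return spsolve(A.tocsr(), source_node * V)


def oxygen_surrogate(mesh, network, coupling, params: OxygenParams,
                     reference: float | None = None):
    """Oxygen field ξ ∈ [0, 1] from perfused-vessel supply.

    Supply is proportional to the perfused vascular density; consumption is
    first-order (faster inside the tumour).  ``reference`` fixes the
    normalisation (e.g. the day-0 healthy level); by default the field is
    scaled by its own maximum.  Returns (ξ, reference_used).
    """
    live = network.functional() & network.perfused
    area = network.wall_area * live
    S_perf = np.asarray(coupling.distribution.T @ area).ravel() / mesh.node_volumes
    tum = mesh.tumour_mask
    decay = np.where(tum, params.uptake_tumour + params.decay_host,
                     params.decay_host)
    raw = _helmholtz_solve(mesh, params.diffusivity, decay, S_perf)
    if reference is None:
        host = ~tum
        reference = float(np.percentile(raw[host], 95)) if host.any() \
            else float(raw.max())
    if reference <= 0:
        return np.zeros(mesh.n_nodes), 0.0
    return np.clip(raw / reference, 0.0, 1.0), reference


def mde_surrogate(mesh, tumour_mask, params: MDEParams,
                  tip_points: np.ndarray | None = None):
    """MDE concentration μ ∈ [0, 1]: secretion by tumour tissue and active
    sprout tips, quasi-steady diffusion with linear decay."""
    src = tumour_mask.astype(float).copy()
    if tip_points is not None and len(tip_points):
        for p in np.clip(tip_points, 0.0, mesh.edge_length):
            corners, w = mesh.trilinear_weights(p)
            src[corners] += w
    if not src.any():
        return np.zeros(mesh.n_nodes)
    raw = _helmholtz_solve(mesh, params.diffusivity, np.full(mesh.n_nodes,
                                                             params.decay), src)
    mx = raw.max()
    return np.clip(raw / mx, 0.0, 1.0) if mx > 0 else raw


# -- ECM dynamics ----------------------------------------------------------

def ecm_depletion_rate(c_i, eps, tumour_mask, p: TissueParams):
    """Drug-driven matrix reduction C (day⁻¹·ϵ units): active only in the
    tumour where ϵ exceeds the depletion threshold; the (c_i − c̄_i) base is
    clamped at zero so fractional exponents never see a negative base."""
    base = np.clip(np.asarray(c_i) - p.ci_threshold, 0.0, None)
    active = tumour_mask & (np.asarray(eps) > p.ecm_threshold)
    return np.where(active, p.delta_d * eps * base ** p.a_d, 0.0)


def ecm_step(eps, mde, xi, c_i, tumour_mask, dt_days: float, p: TissueParams,
             max_substep_days: float = 0.01):
    """Integrate dϵ/dt = λ_ϵ·ξ·exp[−2ϵ/ϵ̄] − δ_ϵ·μ·ϵ − C over ``dt_days``.

    The law is a smooth node-local ODE (μ, ξ, c_i held over the window), so
    classical RK4 sub-steps of ~15 min integrate it far below the 1e-6
    verification tolerance; ϵ is clamped non-negative."""
    eps = np.asarray(eps, float).copy()

    def rate(e):
        e = np.clip(e, 0.0, None)      # RK stages must not leave the domain
        remodel = p.lambda_ecm * xi * np.exp(-2.0 * e / p.ecm_scale)
        degrade = p.delta_ecm * mde * e
        return remodel - degrade - ecm_depletion_rate(c_i, e, tumour_mask, p)

    # drug depletion can be fast (δ_d·Δc_i up to several per day): keep the
    # sub-step well inside the fastest local decay time
    r0 = np.abs(rate(eps)) / np.maximum(eps, 0.1)
    fastest = float(r0.max()) if r0.size else 0.0
    if fastest > 0:
        max_substep_days = min(max_substep_days, 0.1 / fastest)
    n_sub = max(1, int(np.ceil(dt_days / max_substep_days)))
    dt = dt_days / n_sub
    for _ in range(n_sub):
        k1 = rate(eps)
        k2 = rate(eps + 0.5 * dt * k1)
        k3 = rate(eps + 0.5 * dt * k2)
        k4 = rate(eps + dt * k3)
        eps = np.clip(eps + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, None)
    return eps


# -- growth ----------------------------------------------------------------

def growth_strain(xi, eps, p: TissueParams):
    """Modified Gompertz volume growth strain and stretch.

    ϑ_g = G·exp[−β_g·exp(−γ_g ξ)] − G·exp[−β_g] with G = α_g·ϵ^{δ_g};
    λ_g = √(2ϑ_g + 1).  ϑ_g vanishes when ξ = 0 or ϵ = 0 and saturates at
    G·(1 − e^{−β_g}) for abundant oxygen.
    """
    xi = np.asarray(xi, float)
    eps = np.asarray(eps, float)
    G = p.alpha_g * np.clip(eps, 0.0, None) ** p.delta_g
    theta = G * (np.exp(-p.beta_g * np.exp(-p.gamma_g * xi))
                 - np.exp(-p.beta_g))
    assert np.all(theta > -0.5), "growth strain below the kinematic bound"
    return theta, np.sqrt(2.0 * theta + 1.0)


# -- radial solid mechanics ------------------------------------------------

@dataclass
class MechanicsSolution:
    """Radial equilibrium solution mapped back to the 3D domain."""

    R: np.ndarray            # material radial grid (m)
    r: np.ndarray            # deformed radii (m)
    thp_mid: np.ndarray      # κ(J_e − 1) at interval midpoints (Pa)
    lambda_g_mid: np.ndarray
    material_radius: float   # material tumour radius a0
    tumour_volume: float     # deformed tumour volume (m³)
    energy: float
    grad_norm: float

    @property
    def tumour_radius(self) -> float:
        return float(np.interp(self.material_radius, self.R, self.r))

    def displacement_magnitude(self, material_radii) -> np.ndarray:
        """Radial displacement u(R) = r(R) − R, decaying as 1/R² beyond the
        solved ball."""
        Rq = np.asarray(material_radii, float)
        u_out = self.r[-1] - self.R[-1]
        u = np.interp(np.minimum(Rq, self.R[-1]), self.R, self.r) \
            - np.minimum(Rq, self.R[-1])
        far = Rq > self.R[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(far, u_out * (self.R[-1] / np.maximum(Rq, 1e-300)) ** 2,
                         u)
        return u

    def displacement_at(self, material_points, centre) -> np.ndarray:
        X = np.asarray(material_points, float) - centre
        R = np.linalg.norm(X, axis=1)
        u = self.displacement_magnitude(R)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(R[:, None] > 0, X / np.maximum(R, 1e-300)[:, None],
                            0.0)
        return u[:, None] * unit

    def thp_at_spatial(self, spatial_radii) -> np.ndarray:
        """THP sampled at deformed (spatial) radii; zero outside the solved
        ball."""
        r_mid = 0.5 * (self.r[:-1] + self.r[1:])
        d = np.asarray(spatial_radii, float)
        thp = np.interp(d, r_mid, self.thp_mid, left=self.thp_mid[0], right=0.0)
        thp[d > self.r[-1]] = 0.0
        return thp


def _neo_hookean_energy_grad(x, y, m, kappa):
    """W̄(λre, λte) and partials for the modified Neo-Hookean
    W̄ = m/2(Ī₁ − 3) + κ/2(J − 1)² under radial symmetry."""
    J = x * y * y
    B = J ** (-2.0 / 3.0)
    tr = x * x + 2.0 * y * y
    I1b = B * tr
    W = 0.5 * m * (I1b - 3.0) + 0.5 * kappa * (J - 1.0) ** 2
    dBdJ = (-2.0 / 3.0) * J ** (-5.0 / 3.0)
    dJdx, dJdy = y * y, 2.0 * x * y
    dWdx = 0.5 * m * (dBdJ * dJdx * tr + B * 2.0 * x) + kappa * (J - 1.0) * dJdx
    dWdy = 0.5 * m * (dBdJ * dJdy * tr + B * 4.0 * y) + kappa * (J - 1.0) * dJdy
    return W, dWdx, dWdy


def solve_radial_equilibrium(R: np.ndarray, lambda_g_mid: np.ndarray,
                             m_mid: np.ndarray, kappa: float,
                             tol: float = 1e-10, max_newton: int = 60):
    """Equilibrium deformed radii r(R) of the radially symmetric growth
    problem by minimising the total stored energy.

    ``lambda_g_mid`` and ``m_mid`` are interval-midpoint values of the
    isotropic growth stretch and the ECM stiffness modulator.  r(0) = 0;
    the outer surface is traction-free (natural boundary condition of the
    energy).  A damped Newton iteration on the discrete Euler–Lagrange
    system (tridiagonal Hessian by coloured finite differences) is started
    from the volume-matched incompressible profile.  Returns
    (r, energy, ‖gradient‖/‖internal force‖).
    """
    R = np.asarray(R, float)
    L0 = R[-1]
    dR = np.diff(R)
    R_mid = 0.5 * (R[:-1] + R[1:])
    w = 4.0 * np.pi * R_mid ** 2 * dR * lambda_g_mid ** 3

    def energy_grad(r_free):
        r = np.concatenate([[0.0], r_free])
        rp = np.diff(r) / dR
        r_m = 0.5 * (r[:-1] + r[1:])
        x = rp / lambda_g_mid
        y = r_m / (R_mid * lambda_g_mid)
        if np.any(x <= 1e-6) or np.any(y <= 1e-6):
            return np.inf, np.zeros_like(r_free), None
        W, dWdx, dWdy = _neo_hookean_energy_grad(x, y, m_mid, kappa)
        E = float((w * W).sum())
        g = np.zeros(len(r))
        coeff_rp = w * dWdx / lambda_g_mid / dR
        coeff_rm = w * dWdy / (R_mid * lambda_g_mid) * 0.5
        np.add.at(g, np.arange(len(dR)), -coeff_rp + coeff_rm)
        np.add.at(g, np.arange(1, len(r)), coeff_rp + coeff_rm)
        # internal-force scale for the relative convergence check
        scale = float(np.linalg.norm(np.abs(coeff_rp) + np.abs(coeff_rm)))
        return E, g[1:], scale

    # volume-matched (incompressible) initial profile
    vol_g = np.cumsum(np.concatenate(
        [[0.0], lambda_g_mid ** 3 * (R[1:] ** 3 - R[:-1] ** 3)]))
    r = np.cbrt(vol_g)
    r_free = r[1:]

    E, g, scale = energy_grad(r_free)
    for _ in range(max_newton):
        if np.linalg.norm(g) <= tol * max(scale, 1e-300):
            break
        # tridiagonal Jacobian of g by 3-colour finite differences
        n = len(r_free)
        J = np.zeros((3, n))          # banded (1,1) storage
        h = 1e-7 * L0
        for colour in range(3):
            pert = np.zeros(n)
            pert[colour::3] = h
            _, gp, _ = energy_grad(r_free + pert)
            col = (gp - g) / h
            for j in range(colour, n, 3):
                if j > 0:
                    J[0, j] = col[j - 1]      # superdiag entry A[j-1, j]
                J[1, j] = col[j]
                if j < n - 1:
                    J[2, j] = col[j + 1]      # subdiag entry A[j+1, j]
        from scipy.linalg import solve_banded
        try:
            step = solve_banded((1, 1), J, -g)
        except np.linalg.LinAlgError:
            break
        alpha = 1.0
        for _ls in range(40):
            E_new, g_new, scale_new = energy_grad(r_free + alpha * step)
            if np.isfinite(E_new) and E_new <= E + 1e-12 * abs(E) + 1e-300:
                break
            alpha *= 0.5
        else:
            break
        r_free = r_free + alpha * step
        E, g, scale = E_new, g_new, scale_new

    res = minimize(energy_grad_wrapper := (lambda rf: energy_grad(rf)[:2]),
                   r_free, jac=True, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-16}) \
        if np.linalg.norm(g) > 1e-6 * max(scale, 1e-300) else None
    if res is not None and res.fun < E:
        r_free = res.x
        E, g, scale = energy_grad(r_free)

    r = np.concatenate([[0.0], r_free])
    lam_node = np.concatenate([[lambda_g_mid[0]], lambda_g_mid])
    rel = float(np.linalg.norm(g) / max(scale, 1e-300))
    return r, E, rel, lam_node


def solve_mechanics(mesh, theta_g, ecm, params: TissueParams,
                    material_radius: float, n_radial: int = 96
                    ) -> MechanicsSolution:
    """Quasi-static growth mechanics for the (radially reduced) scenario.

    The nodal growth strain is averaged over the tumour region and applied
    uniformly inside the material tumour ball of radius ``material_radius``;
    the stiffness modulator m(ϵ) = μ·ϵ^{a_w} is region-averaged likewise.
    Returns the radial solution mapped back to the 3D mesh through
    :class:`MechanicsSolution`.
    """
    tum = mesh.tumour_mask
    theta_g = np.asarray(theta_g, float)
    theta_t = float(theta_g[tum].mean()) if tum.any() else 0.0
    lam_t = np.sqrt(2.0 * max(theta_t, 0.0) + 1.0)
    ecm = np.asarray(ecm, float)
    eps_floor = 0.02
    eps_t = max(float(ecm[tum].mean()) if tum.any() else 1.0, eps_floor)
    eps_h = max(float(ecm[~tum].mean()) if (~tum).any() else 1.0, eps_floor)
    m_t = params.mu_shear * eps_t ** params.a_w
    m_h = params.mu_shear * eps_h ** params.a_w

    R_out = mesh.edge_length / 2.0
    a0 = material_radius
    inner = np.linspace(0.0, a0, max(8, n_radial // 6))
    outer = a0 * (R_out / a0) ** np.linspace(0.0, 1.0, n_radial)[1:]
    R = np.unique(np.concatenate([inner, outer]))
    R_mid = 0.5 * (R[:-1] + R[1:])
    lam_mid = np.where(R_mid < a0, lam_t, 1.0)
    m_mid = np.where(R_mid < a0, m_t, m_h)
    r, E, gnorm, _ = solve_radial_equilibrium(R, lam_mid, m_mid,
                                              params.kappa_bulk)

    rp = np.diff(r) / np.diff(R)
    r_m = 0.5 * (r[:-1] + r[1:])
    x = rp / lam_mid
    y = r_m / (R_mid * lam_mid)
    J_e = x * y * y
    thp = params.kappa_bulk * (J_e - 1.0)
    r_T = float(np.interp(a0, R, r))
    return MechanicsSolution(R=R, r=r, thp_mid=thp, lambda_g_mid=lam_mid,
                             material_radius=a0,
                             tumour_volume=4.0 / 3.0 * np.pi * r_T ** 3,
                             energy=E, grad_norm=gnorm)


def relative_tumour_volume(volume: float, volume0: float) -> float:
    """V = Vol(t)/Vol(0) − 1."""
    return volume / volume0 - 1.0
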