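"""Drug delivery: bolus, intravascular advection, hindered transvascular and
lymphatic exchange, and the free/bound/internalised extravascular system.

Concentrations are dimensionless fractions of the injected peak c_v-max.
The intravascular solute is advected by the solved blood flow with
first-order upwinding on the network (finite-volume at vascular nodes);
the extravascular free drug diffuses (Stokes–Einstein diffusivity), is
advected by the Darcy velocity, exchanges across the vessel wall through a
cylindrical-pore hindered-transport model, and binds/internalises in the
tumour.  Reactions are integrated implicitly (positivity-preserving).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .units import BOLTZMANN

log = logging.getLogger(__name__)


def stokes_einstein_diffusivity(s_c: float, T: float, mu_I: float) -> float:
    """Free-drug diffusivity D_c = k_B·T/(3π·μ_I·s_c) (m²/s) for a molecule
    of hydrodynamic diameter s_c."""
    if s_c <= 0 or T <= 0 or mu_I <= 0:
        raise ValueError("Stokes-Einstein needs positive size/temperature/viscosity")
    return BOLTZMANN * T / (3.0 * np.pi * mu_I * s_c)


def hindrance_coefficients(s_c, r_p, gamma_p, h, D_c):
    """Hindered transport through cylindrical wall pores.

    With λ_r = s_c/(2 r_p) (molecule diameter over pore diameter):

    * steric partition           Φ(λ) = (1 − λ)²
    * diffusive hindrance        H(λ) = 1 − 2.1044λ + 2.089λ³ − 0.948λ⁵
      (Renkin centreline drag, clamped at 0)
    * diffusive permeability     P_vsc,d = γ_p·Φ·H·D_c/h
    * solvent-drag reflection    σ_f = 1 − W,  W = Φ(2 − Φ)(1 − λ²/3)

    Unhindered limit λ→0 gives (γ_p·D_c/h, 0); full steric exclusion
    s_c ≥ 2·r_p returns (0, 1).
    """
    lam = s_c / (2.0 * r_p)
    if lam >= 1.0:
        log.warning("drug size %.3g m exceeds pore diameter %.3g m: "
                    "full steric exclusion", s_c, 2 * r_p)
        return 0.0, 1.0
    phi = (1.0 - lam) ** 2
    H = max(0.0, 1.0 - 2.1044 * lam + 2.089 * lam ** 3 - 0.948 * lam ** 5)
    P_d = gamma_p * phi * H * D_c / h
    W = phi * (2.0 - phi) * (1.0 - lam ** 2 / 3.0)
    sigma_f = 1.0 - W
    return P_d, min(max(sigma_f, 0.0), 1.0)


def bolus_concentration(t, t_inj, c_v_max, tau_c):
    """Inlet concentration c_v(t) = c_v-max·exp[−(t−t_inj)/τ_c] after the
    injection instant, zero before."""
    t = np.asarray(t, float)
    out = np.where(t >= t_inj, c_v_max * np.exp(-np.maximum(t - t_inj, 0.0)
                                                / tau_c), 0.0)
    return out if out.ndim else float(out)


@dataclass
class DrugState:
    """Concentration fields and cumulative mass-budget diagnostics."""

    c_v: np.ndarray      # per vascular node
    c_f: np.ndarray      # per mesh node
    c_b: np.ndarray
    c_i: np.ndarray
    injected: float = 0.0        # inlet inflow, m³·(c units)
    vascular_out: float = 0.0    # outlet + filtrate efflux from the network
    extravasated: float = 0.0    # ∫Φ_vsc dV dt added to the tissue
    drained: float = 0.0         # lymphatic removal −∫Φ_lmp dV dt
    decayed: float = 0.0         # internalised-drug decay ∫δ_i c_i ϵ dV dt
    cleared: float = 0.0         # bound/internalised drug released with
                                 # regressing tumour tissue

    @classmethod
    def zeros(cls, n_vsc_nodes: int, n_mesh_nodes: int) -> "DrugState":
        return cls(np.zeros(n_vsc_nodes), np.zeros(n_mesh_nodes),
                   np.zeros(n_mesh_nodes), np.zeros(n_mesh_nodes))

    def total_hit(self) -> np.ndarray:
        """c_h = c_b + c_i pointwise."""
        return self.c_b + self.c_i


def total_hit_concentration(state: DrugState, mesh):
    """(c_h field, tumour-integrated scalar ∫_{Ω^T} c_h dV in m³·c units)."""
    c_h = state.total_hit()
    mask = mesh.tumour_mask
    return c_h, float((c_h * mesh.node_volumes)[mask].sum())


# -- intravascular advection ----------------------------------------------

def vascular_node_volumes(network) -> np.ndarray:
    """Blood volume attributed to each vascular node: half of each incident
    non-collapsed segment's lumen volume."""
    vol = np.zeros(network.n_nodes)
    live = network.functional()
    seg_vol = np.pi * network.radius ** 2 * network.lengths * live
    np.add.at(vol, network.node_a, 0.5 * seg_vol)
    np.add.at(vol, network.node_b, 0.5 * seg_vol)
    return vol


def step_intravascular(network, pressures, inlet_value: float, c_v: np.ndarray,
                       dt: float, state: DrugState | None = None) -> np.ndarray:
    """Advance dc_v/dt + v·dc_v/dL = 0 with upwind fluxes at junctions.

    Inlets hold the bolus Dirichlet value; outlets are free outflow
    (dc_v/dL = 0).  Sub-steps internally to the CFL limit.  Filtrate leaving
    the network carries the local concentration (bookkept as vascular
    outflow).
    """
    M = network.n_nodes
    Q = np.where(network.functional(), pressures.Q_vsc, 0.0)
    vol = vascular_node_volumes(network)
    # donor-cell bookkeeping: segment flow a→b when Q>0
    donors = np.where(Q >= 0, network.node_a, network.node_b)
    receivers = np.where(Q >= 0, network.node_b, network.node_a)
    absQ = np.abs(Q)
    out_rate = np.zeros(M)
    np.add.at(out_rate, donors, absQ)
    # node imbalance: external efflux (outlets, filtrate) / influx (inlets)
    meta = getattr(pressures, "meta", None)
    if meta and "KA" in meta:
        # per-endpoint Starling shares, consistent with the fluid solve's
        # junction balance
        KA, dpi, Wp = meta["KA"], meta["dpi"], meta["Wp"]
        q_a = 0.5 * KA * (pressures.p_vsc[network.node_a] - dpi - Wp)
        q_b = 0.5 * KA * (pressures.p_vsc[network.node_b] - dpi - Wp)
    else:
        q_a = q_b = 0.5 * pressures.Q_trv
    trv = np.zeros(M)
    np.add.at(trv, network.node_a, q_a)
    np.add.at(trv, network.node_b, q_b)
    # external efflux = filtrate leaving through the wall (positive part)
    # plus any conservation excess (outlets); reabsorbed interstitial fluid
    # is assumed drug-free on the vascular side
    beta = -trv.copy()
    np.add.at(beta, receivers, absQ)
    np.add.at(beta, donors, -absQ)
    ext_out = np.maximum(trv, 0.0) + np.maximum(beta, 0.0)
    total_out = out_rate + ext_out
    inlet_mask = np.zeros(M, dtype=bool)
    inlet_mask[network.inlets] = True
    donor_is_inlet = inlet_mask[donors]
    receiver_is_inlet = inlet_mask[receivers]

    live_nodes = vol > 0
    with np.errstate(divide="ignore"):
        rate_cap = np.where(live_nodes, total_out / np.maximum(vol, 1e-300), 0.0)
    pos = rate_cap[rate_cap > 0]
    # the CFL step follows the bulk of the network; the few much-stiffer
    # nodes (tiny sprout tips) relax orders of magnitude faster than the
    # step and are held at their local flux equilibrium instead
    bulk_rate = float(np.quantile(pos, 0.95)) if pos.size else 0.0
    n_sub = max(1, int(np.ceil(dt * bulk_rate / 0.9)))
    dts = dt / n_sub
    fast = rate_cap * dts > 0.9
    inlets = network.inlets

    c = c_v.copy()
    for _ in range(n_sub):
        c[inlets] = inlet_value
        influx = np.zeros(M)
        np.add.at(influx, receivers, absQ * c[donors])
        dc = np.where(live_nodes,
                      dts * (influx - total_out * c) / np.maximum(vol, 1e-300),
                      0.0)
        if state is not None:
            # delivered = net solute flux from inlet nodes into the network;
            # outflow = outlet/filtrate efflux from non-inlet nodes
            state.vascular_out += dts * float(
                (ext_out * c)[~inlet_mask].sum())
            flux = absQ * c[donors]
            state.injected += dts * float(flux[donor_is_inlet].sum()
                                          - flux[receiver_is_inlet].sum())
        c = c + dc
        if fast.any():
            c[fast] = influx[fast] / np.maximum(total_out[fast], 1e-300)
        c[inlets] = inlet_value
        if np.any(c < -1e-9):
            raise RuntimeError("negative intravascular concentration: "
                               "advection stepping bug")
        np.clip(c, 0.0, None, out=c)
    return c


def _network_flux_terms(network, pressures):
    """Donor/receiver segment fluxes and per-node external efflux used by
    both intravascular integrators."""
    M = network.n_nodes
    Q = np.where(network.functional(), pressures.Q_vsc, 0.0)
    donors = np.where(Q >= 0, network.node_a, network.node_b)
    receivers = np.where(Q >= 0, network.node_b, network.node_a)
    absQ = np.abs(Q)
    meta = getattr(pressures, "meta", None)
    if meta and "KA" in meta:
        KA, dpi, Wp = meta["KA"], meta["dpi"], meta["Wp"]
        q_a = 0.5 * KA * (pressures.p_vsc[network.node_a] - dpi - Wp)
        q_b = 0.5 * KA * (pressures.p_vsc[network.node_b] - dpi - Wp)
    else:
        q_a = q_b = 0.5 * pressures.Q_trv
    trv = np.zeros(M)
    np.add.at(trv, network.node_a, q_a)
    np.add.at(trv, network.node_b, q_b)
    out_rate = np.zeros(M)
    np.add.at(out_rate, donors, absQ)
    beta = -trv.copy()
    np.add.at(beta, receivers, absQ)
    np.add.at(beta, donors, -absQ)
    ext_out = np.maximum(trv, 0.0) + np.maximum(beta, 0.0)
    return donors, receivers, absQ, out_rate, ext_out


def solve_intravascular_implicit(network, pressures, inlet_value: float,
                                 c_v: np.ndarray, dt: float,
                                 state: DrugState | None = None) -> np.ndarray:
    """Backward-Euler upwind update of the intravascular concentration.

    The bolus decays over hours while the network transit time is seconds,
    so a single unconditionally stable implicit step per exchange window is
    accurate; the upwind matrix is an M-matrix (positivity) and the
    injected/outflow bookkeeping closes the vascular mass budget exactly.
    """
    from scipy.sparse import coo_matrix as _coo
    from scipy.sparse.linalg import spsolve as _spsolve

    M = network.n_nodes
    if M == 0:
        return c_v.copy()
    donors, receivers, absQ, out_rate, ext_out = _network_flux_terms(
        network, pressures)
    vol = vascular_node_volumes(network)
    total_out = out_rate + ext_out
    inlet_mask = np.zeros(M, dtype=bool)
    inlet_mask[network.inlets] = True

    rows = [np.arange(M)]
    cols = [np.arange(M)]
    vals = [vol / dt + total_out]
    keep = ~inlet_mask[receivers]
    rows.append(receivers[keep])
    cols.append(donors[keep])
    vals.append(-absQ[keep])
    A = _coo((np.concatenate(vals),
              (np.concatenate(rows), np.concatenate(cols))),
             shape=(M, M)).tolil()
    rhs = vol / dt * c_v
    # isolated zero-volume, zero-flux nodes (all incident segments
    # collapsed) keep their value
    dead = np.flatnonzero((vol / dt + total_out <= 0) & ~inlet_mask)
    for n in dead:
        A.rows[n] = [n]
        A.data[n] = [1.0]
        rhs[n] = c_v[n]
    for n in network.inlets:
        A.rows[n] = [n]
        A.data[n] = [1.0]
        rhs[n] = inlet_value
    c = _spsolve(A.tocsr(), rhs)
    np.clip(c, 0.0, None, out=c)
    if state is not None:
        flux = absQ * c[donors]
        state.injected += dt * float(flux[inlet_mask[donors]].sum()
                                     - flux[inlet_mask[receivers]].sum())
        state.vascular_out += dt * float((ext_out * c)[~inlet_mask].sum())
    return c


# -- exchange rates --------------------------------------------------------

def transvascular_solute_rate(c_v, c_f, p_eff, p_int, K_vsc, P_vsc_d,
                              sigma_f, S_vsc):
    """Starling solute flux per unit volume through the vessel wall (Eq of
    the pore model): diffusive P·S·(c_v − c_f) plus solvent drag with the
    upwind concentration (c_v when filtering outward, c_f when reabsorbing).
    """
    dp = np.asarray(p_eff) - np.asarray(p_int)
    c_up = np.where(dp > 0, c_v, c_f)
    return (P_vsc_d * S_vsc * (np.asarray(c_v) - np.asarray(c_f))
            + K_vsc * S_vsc * (1.0 - sigma_f) * dp * c_up)


def lymphatic_solute_rate(c_f, p_lmp, p_int, K_lmp, S_lmp, sigma_f_lmp=0.0):
    """Lymphatic drainage solute rate per unit volume (a sink when
    p_int > p_lmp)."""
    return K_lmp * S_lmp * (1.0 - sigma_f_lmp) * (np.asarray(p_lmp)
                                                  - np.asarray(p_int)) * c_f


# -- extravascular stepping ------------------------------------------------

def _exact_reaction_step(c_f, c_b, c_i, kon, koff, kint, a_i, dt):
    """Exact update of the linear binding/internalisation kinetics.

    The (c_f, c_b) block is autonomous with closed-form eigenvalues; c_i is
    then a scalar linear equation forced by the two c_b exponentials.
    Exactness keeps the operator-split scheme's only error in the transport
    coupling and preserves positivity for any time step.
    """
    c_f = np.asarray(c_f, float)
    c_b = np.asarray(c_b, float)
    c_i = np.asarray(c_i, float)
    kon = np.broadcast_to(np.asarray(kon, float), c_f.shape)
    koff = np.broadcast_to(np.asarray(koff, float), c_f.shape)
    kint = np.broadcast_to(np.asarray(kint, float), c_f.shape)
    a_i = np.broadcast_to(np.asarray(a_i, float), c_f.shape)
    # outside the reactive region the kinetics are the identity (plus pure
    # c_i decay); the eigen formulas below assume distinct decay rates,
    # which holds whenever k_on, k_off > 0
    inert = (kon + koff + kint) == 0.0
    s = kon + koff + kint
    disc = np.sqrt(np.maximum(s * s - 4.0 * kon * kint, 0.0))
    l1 = 0.5 * (s + disc)              # decay rates (≥ 0)
    l2 = 0.5 * (s - disc)
    sep = np.maximum(l1 - l2, 1e-300)
    # eigenvector decomposition of [[-kon, koff], [kon, -(koff+kint)]]
    # written against the decay rates l1, l2 (eigenvalues −l1, −l2)
    e1 = np.exp(-l1 * dt)
    e2 = np.exp(-l2 * dt)
    # coefficients of c_f(t) = A1 e^{-l1 t} + A2 e^{-l2 t}, likewise c_b
    df0 = -kon * c_f + koff * c_b      # c_f'(0)
    db0 = kon * c_f - (koff + kint) * c_b
    A1 = (-l2 * c_f - df0) / sep
    A2 = (l1 * c_f + df0) / sep
    B1 = (-l2 * c_b - db0) / sep
    B2 = (l1 * c_b + db0) / sep
    nf = A1 * e1 + A2 * e2
    nb = B1 * e1 + B2 * e2
    # c_i' = kint·c_b(t) − a_i·c_i
    ea = np.exp(-a_i * dt)

    def _conv(l, el):
        d = a_i - l
        small = np.abs(d) < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(small, dt * np.exp(-l * dt),
                           (el - ea) / np.where(small, 1.0, d))
        return out

    ni = c_i * ea + kint * (B1 * _conv(l1, e1) + B2 * _conv(l2, e2))
    nf = np.where(inert, c_f, nf)
    nb = np.where(inert, c_b, nb)
    ni = np.where(inert, c_i * ea, ni)
    return (np.clip(nf, 0.0, None), np.clip(nb, 0.0, None),
            np.clip(ni, 0.0, None))

def _advect_diffuse(mesh, c, v, D, dt):
    """Explicit conservative upwind advection + FD diffusion, zero-flux
    boundaries.

    Diffusion is the mirrored 7-point Laplacian; advection uses upwind
    donor-cell face fluxes (velocity averaged to faces), which telescope
    exactly, so transport conserves total mass to round-off (the physical
    model assumes a divergence-free Darcy velocity).
    """
    shape = mesh.grid_shape()
    f = c.reshape(shape)
    h = mesh.h
    out = f.copy()
    # diffusion: 7-point Laplacian, mirrored (Neumann) at the boundary
    lap = np.zeros_like(f)
    for ax in range(3):
        up = np.concatenate([f.take([1], axis=ax), f], axis=ax)
        up = np.delete(up, -1, axis=ax)
        dn = np.concatenate([f, f.take([-2], axis=ax)], axis=ax)
        dn = np.delete(dn, 0, axis=ax)
        lap += (up + dn - 2 * f)
    out += dt * D / h ** 2 * lap
    # finite-volume node widths along an axis: h/2 at the two boundaries
    w1 = np.full(shape[0], h)
    w1[0] = w1[-1] = h / 2.0
    vv = v.reshape(shape + (3,))
    for ax in range(3):
        vn = vv[..., ax]
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        vf = 0.5 * (vn[tuple(lo)] + vn[tuple(hi)])          # face velocity
        flux = (np.maximum(vf, 0.0) * f[tuple(lo)]
                + np.minimum(vf, 0.0) * f[tuple(hi)])
        wshape = [1, 1, 1]
        wshape[ax] = shape[ax]
        w = w1.reshape(wshape)
        df = np.zeros_like(f)
        df[tuple(lo)] -= flux
        df[tuple(hi)] += flux
        out += dt * df / w
    return out.reshape(-1)


def step_extravascular(mesh, state: DrugState, v_int, D_c, exchange,
                       k_on, k_off, k_int, delta_i, ecm,
                       tumour_mask, dt: float) -> None:
    """Advance c_f, c_b, c_i by one (sub-stepped) time increment.

    ``exchange`` = (a_vsc, b_vsc, a_lmp, b_lmp): the transvascular and
    lymphatic exchange rates written in the affine form Φ = a − b·c_f with
    a, b ≥ 0 per node (held constant over the window).  The c_f-proportional
    part is integrated implicitly, which keeps the update unconditionally
    stable and positive even for hyperpermeable walls; transport uses
    explicit upwinding/FD under its own CFL sub-stepping.  Reactions are
    integrated exactly.  Updates ``state`` in place with budget
    accumulators.
    """
    a_v, b_v, a_l, b_l = [np.asarray(x, float) for x in exchange]
    h2 = mesh.h ** 2
    vmax = float(np.abs(v_int).max()) if len(v_int) else 0.0
    # combined explicit bound: 6-point diffusion stencil + 3-axis upwinding
    stab = 0.8 / (6.0 * D_c / h2 + 3.0 * vmax / mesh.h + 1e-300)
    n_sub = max(1, int(np.ceil(dt / stab)))
    if n_sub > 1:
        log.debug("extravascular step sub-divided %d-fold (dt=%.3g)", n_sub, dt)
    dts = dt / n_sub
    vols = mesh.node_volumes
    kon = np.where(tumour_mask, k_on, 0.0)
    koff = np.where(tumour_mask, k_off, 0.0)
    kint = np.where(tumour_mask, k_int, 0.0)
    di = np.where(tumour_mask, delta_i, 0.0)

    c_f, c_b, c_i = state.c_f, state.c_b, state.c_i
    for _ in range(n_sub):
        c_f = _advect_diffuse(mesh, c_f, v_int, D_c, dts)
        c_f = (c_f + dts * (a_v + a_l)) / (1.0 + dts * (b_v + b_l))
        np.clip(c_f, 0.0, None, out=c_f)
        phi_v = a_v - b_v * c_f
        phi_l = a_l - b_l * c_f
        state.extravasated += dts * float((phi_v * vols).sum())
        state.drained += -dts * float((phi_l * vols).sum())
        ci_old = c_i
        nf, nb, ni = _exact_reaction_step(c_f, c_b, c_i, kon, koff, kint,
                                          di * ecm, dts)
        # decay bookkeeping from mass conservation of the closed kinetics
        state.decayed += float((((c_f + c_b + ci_old) - (nf + nb + ni))
                                * vols).sum())
        c_f, c_b, c_i = nf, nb, ni
    if min(c_f.min(initial=0), c_b.min(initial=0), c_i.min(initial=0)) < -1e-9:
        raise RuntimeError("negative extravascular concentration")
    state.c_f, state.c_b, state.c_i = c_f, c_b, c_i
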