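"""Coupled steady vascular / transvascular / interstitial / lymphatic flow.

One sparse linear solve determines the vascular nodal pressures p_vsc and
the interstitial nodal pressures p_int simultaneously:

* Poiseuille flow on every non-collapsed segment, Q̇ = −(πR⁴/8μL)·Δp;
* Starling transvascular filtration Q̇_trv = K_vsc·A_vsc·(p_eff − p_int)
  with p_eff = p̄_vsc − σ_o(π_vsc − π_int) and K_vsc = γ_p r_p²/(8 μ_P h);
* Darcy flow in the tissue (7-point finite differences on the structured
  grid, face conductivity averaged between nodes);
* a homogeneous lymphatic sink K_lmp·S_lmp·(p_lmp − p_int) per unit volume
  (zero S_lmp inside the tumour).

Default boundary conditions: Dirichlet pressures at vascular inlets/outlets
and far-field p_int = 0 on the tissue boundary (a sealed Neumann boundary is
available for verification problems).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix, eye, bmat
from scipy.sparse.linalg import spsolve

from .network import STATE_COLLAPSED
from .params import FluidParams, LymphParams


class SolvabilityError(RuntimeError):
    pass


def segment_conductance(R, L, mu):
    """Poiseuille conductance πR⁴/(8 μ L) of a capillary segment
    (m³ s⁻¹ Pa⁻¹); Q̇ = −conductance·Δp."""
    R, L = np.asarray(R, float), np.asarray(L, float)
    if np.any(R <= 0) or np.any(L <= 0) or mu <= 0:
        raise ValueError("segment conductance needs positive R, L and μ")
    return np.pi * R ** 4 / (8.0 * mu * L)


def wall_conductivity(r_p, gamma_p, h, mu_plasma):
    """Pore-model hydraulic conductivity of the vessel wall,
    K_vsc = γ_p r_p² / (8 μ_P h)  (m Pa⁻¹ s⁻¹)."""
    if np.any(np.asarray(h) <= 0) or mu_plasma <= 0:
        raise ValueError("wall thickness and plasma viscosity must be positive")
    return np.asarray(gamma_p) * np.asarray(r_p) ** 2 / (8.0 * mu_plasma * h)


def lymph_segment_flow(R, L, dp, mu_I):
    """Hagen–Poiseuille lymph flow Q̇_lmp = −πR⁴Δp/(8 μ_I L) for the optional
    discrete lymphatic mode."""
    return -segment_conductance(R, L, mu_I) * dp


@dataclass
class PressureState:
    """Solved pressures and derived flows/velocities."""

    p_int: np.ndarray            # Pa, per mesh node
    p_vsc: np.ndarray            # Pa, per vascular node
    p_eff: np.ndarray            # Pa, per segment
    Q_vsc: np.ndarray            # m³/s per segment, positive a→b
    dp_vsc: np.ndarray           # Pa per segment (p_a − p_b)
    Q_trv: np.ndarray            # m³/s per segment (filtration out of vessel)
    Q_lmp_node: np.ndarray       # m³/s per mesh node (drainage, ≥0 out)
    v_vsc: np.ndarray            # m/s mean blood velocity per segment
    v_int: np.ndarray            # m/s Darcy velocity per mesh node (vector)
    K_int_node: np.ndarray
    boundary_outflow: float
    residual: float
    meta: dict = field(default_factory=dict)

    def averaged_ifv(self, mask) -> float:
        """Mean |v_int| (m/s) over a nodal mask."""
        return float(np.linalg.norm(self.v_int[mask], axis=1).mean())

    def averaged_ifp(self, mask) -> float:
        return float(self.p_int[mask].mean())


def _tissue_operator(mesh, K_node):
    """FD Darcy operator entries: rows/cols/vals of Σ_f c_f (p_j − p_i)."""
    shape = mesh.grid_shape()
    K = K_node.reshape(shape)
    idx = np.arange(mesh.n_nodes).reshape(shape)
    rows, cols, vals = [], [], []
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        i, j = idx[tuple(sl_lo)].ravel(), idx[tuple(sl_hi)].ravel()
        # face conductance c = K_face * (A/h) = K_face * h
        c = 0.5 * (K[tuple(sl_lo)] + K[tuple(sl_hi)]).ravel() * mesh.h
        rows.extend([i, i, j, j])
        cols.extend([j, i, i, j])
        vals.extend([c, -c, c, -c])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return coo_matrix((vals, (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()


def solve_coupled_pressures(network, mesh, coupling, lymph: LymphParams,
                            params: FluidParams, *,
                            sealed_boundary: bool = False,
                            boundary_pressure: float = 0.0,
                            extra_source_LpS: np.ndarray | None = None,
                            extra_source_p: float = 0.0) -> PressureState:
    """Solve the coupled pressure problem; returns a :class:`PressureState`.

    ``extra_source_LpS`` adds a homogeneous distributed Starling source
    (conductivity·density per unit volume, at pressure ``extra_source_p``) —
    used for verification against radially symmetric closed forms.
    """
    N = mesh.n_nodes
    M = network.n_nodes
    tum = mesh.tumour_mask
    K_node = np.where(tum, params.K_int_tumour, params.K_int_host)
    L_tt = _tissue_operator(mesh, K_node)

    # lymphatic sink coefficient per node (m³/s/Pa)
    S_lmp = np.where(tum, lymph.S_lmp_tumour, lymph.S_lmp_host)
    lam = lymph.K_lmp * S_lmp * mesh.node_volumes
    if extra_source_LpS is not None:
        xsrc = np.asarray(extra_source_LpS) * mesh.node_volumes
    else:
        xsrc = np.zeros(N)

    # live segments and wall conductance
    live = network.functional()
    area = network.wall_area
    Kv = np.where(live,
                  wall_conductivity(network.pore_radius, network.pore_fraction,
                                    network.wall_thickness, params.mu_plasma),
                  0.0)
    KA = Kv * area                                  # m³/s/Pa per segment
    dpi = (params.pi_vascular - params.pi_interstitial) * params.sigma_osmotic

    W = coupling.midpoint_weights                   # (n_seg, N) convex rows
    n_seg = network.n_segments
    g = np.zeros(n_seg)
    if n_seg:
        g[live] = segment_conductance(network.radius[live],
                                      network.lengths[live], params.mu_blood)

    # vascular graph Laplacian
    a, b = network.node_a, network.node_b
    G_vv = coo_matrix((np.r_[g, g, -g, -g],
                       (np.r_[a, b, a, b], np.r_[b, a, a, b])),
                      shape=(M, M)).tocsr() if n_seg else csr_matrix((M, M))

    # endpoint averaging matrix E (n_seg, M): p̄_vsc = E p_vsc
    if n_seg:
        E = coo_matrix((np.r_[np.full(n_seg, .5), np.full(n_seg, .5)],
                        (np.r_[np.arange(n_seg), np.arange(n_seg)],
                         np.r_[a, b])), shape=(n_seg, M)).tocsr()
    else:
        E = csr_matrix((0, M))
    KAd = csr_matrix((n_seg, n_seg))
    if n_seg:
        KAd = csr_matrix((KA, (np.arange(n_seg), np.arange(n_seg))),
                         shape=(n_seg, n_seg))

    # blocks: tissue rows then vascular rows.  The transvascular exchange is
    # assembled as pairwise endpoint↔node fluxes
    # q = ½·K_vsc·A·w_si·(p_vsc,n − σΔπ − p_int,i), which sums to the
    # Starling flux K·A·(p_eff − p̃_int) per segment while keeping the
    # coupled matrix an M-matrix (discrete maximum principle) even for
    # hyperpermeable walls.
    trv_t = np.asarray((W.T @ KA)).ravel()          # Σ_s KA·w_si per node
    trv_v = np.asarray((E.T @ KA)).ravel()          # Σ_s ½KA per vasc node
    A_tt = L_tt - csr_matrix((lam + xsrc + trv_t,
                              (np.arange(N), np.arange(N))), shape=(N, N))
    A_tv = W.T @ KAd @ E
    A_vt = E.T @ KAd @ W
    A_vv = G_vv - csr_matrix((trv_v, (np.arange(M), np.arange(M))),
                             shape=(M, M))
    b_t = -lam * lymph.p_lmp - xsrc * extra_source_p + trv_t * dpi
    b_v = -trv_v * dpi

    if M:
        A = bmat([[A_tt, A_tv], [A_vt, A_vv]]).tolil()
        rhs = np.concatenate([b_t, b_v])
    else:
        A = A_tt.tolil()
        rhs = b_t

    # Dirichlet rows
    dir_idx = []
    dir_val = []
    if not sealed_boundary:
        bnd = np.flatnonzero(mesh.boundary_mask)
        dir_idx.extend(bnd.tolist())
        dir_val.extend([boundary_pressure] * len(bnd))
    for n in network.inlets:
        dir_idx.append(N + n)
        dir_val.append(params.p_inlet)
    for n in network.outlets:
        dir_idx.append(N + n)
        dir_val.append(params.p_outlet)
    # pin fully decoupled vascular nodes (all incident segments collapsed)
    diag = A.diagonal()
    for n in range(M):
        if N + n not in dir_idx and diag[N + n] == 0.0:
            dir_idx.append(N + n)
            dir_val.append(0.0)

    if not dir_idx and not np.any(lam) and not np.any(xsrc) and not np.any(KA):
        raise SolvabilityError(
            "no Dirichlet anchor and no lymphatic/transvascular sink: the "
            "pressure problem is singular")

    for i, v in zip(dir_idx, dir_val):
        A.rows[i] = [i]
        A.data[i] = [1.0]
        rhs[i] = v
    A = A.tocsr()
    x = spsolve(A, rhs)
    res = float(np.linalg.norm(A @ x - rhs)
                / max(np.linalg.norm(rhs), 1e-300))
    if not np.all(np.isfinite(x)):
        raise SolvabilityError("singular coupled pressure system")

    p_int, p_vsc = x[:N], x[N:]
    p_eff = (E @ p_vsc) - dpi if n_seg else np.zeros(0)
    dp = p_vsc[a] - p_vsc[b] if n_seg else np.zeros(0)
    Q = g * dp
    Q_trv = KA * (p_eff - (W @ p_int)) if n_seg else np.zeros(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_vsc = np.where(network.radius > 0,
                         Q / (np.pi * network.radius ** 2), 0.0)
    v_int = -K_node[:, None] * mesh.gradient(p_int)
    Q_lmp = lam * (p_int - lymph.p_lmp)

    # net outflow through the tissue boundary: face flux into boundary nodes
    # plus the transvascular/lymphatic deposits landing on them
    div_all = L_tt @ p_int
    trv_dep = np.asarray(A_tv @ p_vsc).ravel() - trv_t * (p_int + dpi)
    bnd_mask = mesh.boundary_mask if not sealed_boundary \
        else np.zeros(N, dtype=bool)
    boundary_outflow = float((div_all[bnd_mask] + trv_dep[bnd_mask]
                              - Q_lmp[bnd_mask]).sum()) if bnd_mask.any() else 0.0

    return PressureState(p_int=p_int, p_vsc=p_vsc, p_eff=p_eff, Q_vsc=Q,
                         dp_vsc=dp, Q_trv=Q_trv, Q_lmp_node=Q_lmp,
                         v_vsc=v_vsc, v_int=v_int, K_int_node=K_node,
                         boundary_outflow=boundary_outflow, residual=res,
                         meta={"dpi": dpi, "KA": KA, "g": g, "Kv": Kv,
                               "Wp": (W @ p_int) if n_seg else np.zeros(0),
                               "A": A, "rhs": rhs})


def interstitial_velocity(mesh, p_int, K_int_node) -> np.ndarray:
    """Nodal Darcy velocity v_int = −K_int ∂p_int/∂X (m/s)."""
    return -np.asarray(K_int_node)[:, None] * mesh.gradient(p_int)


def junction_imbalance(network, state: PressureState) -> np.ndarray:
    """Net flow residual Σ Q̇_in − Σ Q̇_out − Q̇_trv share at every interior,
    inlet-connected vascular node (should vanish at the solution)."""
    M = network.n_nodes
    net = np.zeros(M)
    np.add.at(net, network.node_a, -state.Q_vsc)
    np.add.at(net, network.node_b, state.Q_vsc)
    KA, dpi, Wp = state.meta["KA"], state.meta["dpi"], state.meta["Wp"]
    q_a = 0.5 * KA * (state.p_vsc[network.node_a] - dpi - Wp)
    q_b = 0.5 * KA * (state.p_vsc[network.node_b] - dpi - Wp)
    np.add.at(net, network.node_a, -q_a)
    np.add.at(net, network.node_b, -q_b)
    interior = np.ones(M, dtype=bool)
    interior[network.inlets] = False
    interior[network.outlets] = False
    return net[interior]
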