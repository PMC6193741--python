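"""Segment-to-element coupling between the 1D network and the 3D mesh.

Each vascular segment is sampled at quadrature points along its axis (at
most half a grid spacing apart); each point deposits its share of the wall
surface area onto the corner nodes of the containing element with trilinear
weights.  The resulting convex row-stochastic distribution matrix is used
both to spread transvascular sources onto tissue nodes and (as its adjoint)
to sample interstitial pressure/concentration along the segment —
first-order consistent and symmetric in the coupled solve.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix


class EmbeddingError(ValueError):
    pass


class CouplingMap:
    """Coupling weights and vascular-density fields for one (mesh, network).

    Attributes
    ----------
    distribution : (n_segments, n_nodes) csr_matrix
        Convex weights (rows sum to 1) mapping segment quantities to nodes.
    wall_area : (n_segments,) ndarray
        A_vsc = 2πR·L per segment (m²).
    S_vsc_node : (n_nodes,) ndarray
        Vascular density: wall area per nodal tissue volume (1/m).
    S_vsc_elem : (n_elements,) ndarray
        Wall area per element volume (1/m).
    """

    def __init__(self, distribution, midpoint_weights, wall_area, S_vsc_node,
                 S_vsc_elem, mean_radius):
        self.distribution = distribution
        self.midpoint_weights = midpoint_weights
        self.wall_area = wall_area
        self.S_vsc_node = S_vsc_node
        self.S_vsc_elem = S_vsc_elem
        self.mean_radius = mean_radius

    def interstitial_area(self) -> np.ndarray:
        """A_int = 2πR̄/S_vsc per element (m²); inf where avascular."""
        with np.errstate(divide="ignore"):
            return np.where(self.S_vsc_elem > 0,
                            2 * np.pi * self.mean_radius / np.maximum(
                                self.S_vsc_elem, 1e-300), np.inf)


def embed_network(mesh, network) -> CouplingMap:
    """Couple every vascular segment to its host elements.

    Raises :class:`EmbeddingError` naming the first vascular node found
    outside the tissue domain.
    """
    eps = 1e-12 * max(mesh.edge_length, 1.0)
    outside = np.flatnonzero(
        (network.nodes < -eps).any(axis=1)
        | (network.nodes > mesh.edge_length + eps).any(axis=1))
    if len(outside):
        raise EmbeddingError(
            f"vascular node {outside[0]} at {network.nodes[outside[0]]} lies "
            "outside the tissue domain")

    n_seg = network.n_segments
    n_nodes = mesh.n_nodes
    area = network.wall_area
    S_elem = np.zeros(mesh.n_elements)
    if n_seg:
        pa = np.clip(network.nodes[network.node_a], 0.0, mesh.edge_length)
        pb = np.clip(network.nodes[network.node_b], 0.0, mesh.edge_length)
        lengths = network.lengths
        nq = np.maximum(1, np.ceil(lengths / (0.5 * mesh.h)).astype(int))
        seg_of = np.repeat(np.arange(n_seg), nq)
        # in-segment quadrature abscissae (midpoint rule, nq points each)
        offs = np.concatenate([np.zeros(1), np.cumsum(nq)])[:-1]
        local = np.arange(nq.sum()) - np.repeat(offs, nq)
        t = (local + 0.5) / nq[seg_of]
        pts = pa[seg_of] + t[:, None] * (pb[seg_of] - pa[seg_of])
        frac = 1.0 / nq[seg_of]
        corners, w = mesh.trilinear_weights_batch(pts)
        dist = csr_matrix((np.repeat(frac, 8) * w.ravel(),
                           (np.repeat(seg_of, 8), corners.ravel())),
                          shape=(n_seg, n_nodes))
        dist.sum_duplicates()
        n2 = mesh.n
        e = np.minimum((pts / mesh.h).astype(int), n2 - 1)
        elem_idx = (e[:, 0] * n2 + e[:, 1]) * n2 + e[:, 2]
        np.add.at(S_elem, elem_idx, area[seg_of] * frac)
        mids = np.clip(network.midpoints, 0.0, mesh.edge_length)
        mc, mw = mesh.trilinear_weights_batch(mids)
        mid = csr_matrix((mw.ravel(),
                          (np.repeat(np.arange(n_seg), 8), mc.ravel())),
                         shape=(n_seg, n_nodes))
        mid.sum_duplicates()
    else:
        dist = csr_matrix((n_seg, n_nodes))
        mid = csr_matrix((n_seg, n_nodes))
    S_elem /= mesh.element_volume
    S_node = np.asarray(dist.T @ area).ravel() / mesh.node_volumes
    mean_r = float(network.radius.mean()) if n_seg else 0.0
    return CouplingMap(dist, mid, area, S_node, S_elem, mean_r)
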