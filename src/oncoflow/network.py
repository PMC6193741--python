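"""Synthetic 1D vascular networks and their CSV I/O.

A network is a graph of vascular nodes joined by straight capillary
segments.  The synthetic generator places nodes uniformly at random over the
tissue block, guarantees connectivity through a minimum-spanning backbone of
the nearest-neighbour graph, and then adds the shortest unused
nearest-neighbour links until the requested segment density is reached.
Inlets and outlets sit on opposite domain faces.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial import cKDTree

STATE_UNCOMPRESSED = 0
STATE_COMPRESSED = 1
STATE_COLLAPSED = 2
_STATE_NAMES = {0: "uncompressed", 1: "compressed", 2: "collapsed"}
_STATE_CODES = {v: k for k, v in _STATE_NAMES.items()}
_ROLE_NAMES = {0: "interior", 1: "inlet", 2: "outlet"}
_ROLE_CODES = {v: k for k, v in _ROLE_NAMES.items()}

ROLE_INTERIOR, ROLE_INLET, ROLE_OUTLET = 0, 1, 2


class NetworkGenerationError(RuntimeError):
    pass


class VascularNetwork:
    """1D capillary graph with per-segment wall geometry and state flags.

    Node arrays: ``nodes`` (M, 3) current positions (m), ``material_nodes``
    reference positions, ``roles`` (inlet/outlet/interior).  Segment arrays:
    endpoint indices, lumen radius ``radius`` (m), remodelled reference
    radius ``base_radius``, wall thickness, pore radius/fraction, mechanical
    ``state`` and a ``perfused`` flag.
    """

    def __init__(self, nodes, node_a, node_b, radius, wall_thickness,
                 pore_radius, pore_fraction, state=None, roles=None):
        self.nodes = np.asarray(nodes, dtype=float).reshape(-1, 3)
        self.material_nodes = self.nodes.copy()
        self.node_a = np.asarray(node_a, dtype=int)
        self.node_b = np.asarray(node_b, dtype=int)
        n_seg = len(self.node_a)
        self.radius = np.broadcast_to(np.asarray(radius, float), (n_seg,)).copy()
        self.base_radius = self.radius.copy()
        self.wall_thickness = np.broadcast_to(
            np.asarray(wall_thickness, float), (n_seg,)).copy()
        self.pore_radius = np.broadcast_to(
            np.asarray(pore_radius, float), (n_seg,)).copy()
        self.pore_fraction = np.broadcast_to(
            np.asarray(pore_fraction, float), (n_seg,)).copy()
        self.state = (np.zeros(n_seg, dtype=int) if state is None
                      else np.asarray(state, dtype=int).copy())
        self.roles = (np.zeros(len(self.nodes), dtype=int) if roles is None
                      else np.asarray(roles, dtype=int).copy())
        self.perfused = np.ones(n_seg, dtype=bool)
        self._validate()

    def _validate(self):
        if np.any(self.node_a < 0) or np.any(self.node_b >= len(self.nodes)) \
                or np.any(self.node_b < 0) or np.any(self.node_a >= len(self.nodes)):
            raise ValueError("segment references a non-existent node")
        live = self.state != STATE_COLLAPSED
        if np.any(self.radius[live] <= 0) or np.any(self.wall_thickness[live] <= 0):
            raise ValueError("non-collapsed segments need positive radius and "
                             "wall thickness")

    # -- geometry ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.node_a)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.nodes[self.node_b] - self.nodes[self.node_a],
                              axis=1)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.nodes[self.node_a] + self.nodes[self.node_b])

    @property
    def wall_area(self) -> np.ndarray:
        """Per-segment vessel wall surface area A_vsc = 2πR·L (m²)."""
        return 2.0 * np.pi * self.radius * self.lengths

    @property
    def inlets(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_INLET)

    @property
    def outlets(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_OUTLET)

    def functional(self) -> np.ndarray:
        """Boolean mask of non-collapsed segments."""
        return self.state != STATE_COLLAPSED

    def adjacency(self, mask=None):
        """Sparse node adjacency over (a subset of) segments."""
        if mask is None:
            mask = np.ones(self.n_segments, dtype=bool)
        a, b = self.node_a[mask], self.node_b[mask]
        data = np.ones(len(a))
        m = coo_matrix((np.r_[data, data], (np.r_[a, b], np.r_[b, a])),
                       shape=(self.n_nodes, self.n_nodes))
        return m.tocsr()

    def inlet_connected_nodes(self) -> np.ndarray:
        """Nodes reachable from any inlet through non-collapsed segments."""
        _, labels = connected_components(self.adjacency(self.functional()),
                                         directed=False)
        inlet_labels = np.unique(labels[self.inlets])
        return np.isin(labels, inlet_labels)

    def displace(self, displacement: np.ndarray) -> None:
        """Advect vascular nodes with a tissue displacement sampled at their
        material positions."""
        self.nodes = self.material_nodes + displacement

    def add_node(self, material_pos, role: int = ROLE_INTERIOR) -> int:
        """Append a vascular node (material coordinates); returns its index."""
        self.material_nodes = np.vstack([self.material_nodes, material_pos])
        self.nodes = np.vstack([self.nodes, material_pos])
        self.roles = np.append(self.roles, role)
        return self.n_nodes - 1

    def add_segment(self, a: int, b: int, radius: float,
                    template: int | None = None, **wall) -> int:
        """Append a segment; wall properties copied from a template segment
        unless overridden."""
        def prop(name, default):
            if name in wall:
                return wall[name]
            if template is not None and self.n_segments:
                return getattr(self, name)[template]
            return default

        self.node_a = np.append(self.node_a, a)
        self.node_b = np.append(self.node_b, b)
        self.radius = np.append(self.radius, radius)
        self.base_radius = np.append(self.base_radius, radius)
        self.wall_thickness = np.append(self.wall_thickness,
                                        prop("wall_thickness", 5e-6))
        self.pore_radius = np.append(self.pore_radius,
                                     prop("pore_radius", 1.5e-7))
        self.pore_fraction = np.append(self.pore_fraction,
                                       prop("pore_fraction", 0.03))
        self.state = np.append(self.state, STATE_UNCOMPRESSED)
        self.perfused = np.append(self.perfused, True)
        return self.n_segments - 1

    def copy(self) -> "VascularNetwork":
        net = VascularNetwork(self.material_nodes, self.node_a, self.node_b,
                              self.radius, self.wall_thickness,
                              self.pore_radius, self.pore_fraction,
                              state=self.state, roles=self.roles)
        net.nodes = self.nodes.copy()
        net.base_radius = self.base_radius.copy()
        net.perfused = self.perfused.copy()
        return net


def generate_network(seed: int, n_segments: int, domain, *,
                     radius_mean: float = 5.0e-6,
                     radius_jitter: float = 0.1,
                     wall_thickness: float = 5.0e-6,
                     pore_radius: float = 1.5e-7,
                     pore_fraction: float = 0.06,
                     margin_frac: float = 0.04,
                     k_neighbours: int = 6) -> VascularNetwork:
    """Seeded uniform-random capillary network spanning the tissue block.

    Nodes are uniform over the domain (with a small wall margin); an MST over
    the k-nearest-neighbour graph guarantees connectivity and the shortest
    unused kNN links are added as cross-links up to ``n_segments`` segments.
    The same seed reproduces the network bitwise.
    """
    if n_segments < 1:
        raise NetworkGenerationError("need at least one segment")
    rng = np.random.default_rng(seed)
    E = domain.edge_length
    lo, hi = margin_frac * E, (1 - margin_frac) * E

    def _radii(n):
        r = radius_mean * (1 + radius_jitter * rng.standard_normal(n))
        return np.clip(r, 0.4 * radius_mean, 2.5 * radius_mean)

    if n_segments == 1:
        nodes = np.array([[lo, E / 2, E / 2], [hi, E / 2, E / 2]])
        net = VascularNetwork(nodes, [0], [1], _radii(1), wall_thickness,
                              pore_radius, pore_fraction,
                              roles=[ROLE_INLET, ROLE_OUTLET])
        return net

    n_nodes = max(3, int(round(0.75 * n_segments)) + 1)
    for _attempt in range(8):
        pts = lo + (hi - lo) * rng.random((n_nodes, 3))
        k = min(k_neighbours + 1, n_nodes)
        dist, idx = cKDTree(pts).query(pts, k=k)
        rows = np.repeat(np.arange(n_nodes), k - 1)
        cols = idx[:, 1:].ravel()
        w = dist[:, 1:].ravel()
        graph = coo_matrix((w, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()
        n_comp, _ = connected_components(graph, directed=False)
        if n_comp == 1:
            break
    else:
        raise NetworkGenerationError(
            "could not build a connected nearest-neighbour graph after 8 "
            f"retries (n_nodes={n_nodes}); increase k_neighbours")

    mst = minimum_spanning_tree(graph).tocoo()
    edges = {(min(a, b), max(a, b)) for a, b in zip(mst.row, mst.col)}
    # candidate cross-links: unused kNN edges, shortest first (deterministic
    # tie-break on the index pair)
    cand = {}
    for r, c, d in zip(rows, cols, w):
        key = (min(r, c), max(r, c))
        if key not in edges:
            cand[key] = d
    order = sorted(cand, key=lambda key: (cand[key], key))
    for key in order:
        if len(edges) >= n_segments:
            break
        edges.add(key)
    if len(edges) < n_segments:
        raise NetworkGenerationError(
            f"only {len(edges)} distinct links available for {n_segments} "
            "requested segments; increase k_neighbours or lower n_segments")
    edge_arr = np.array(sorted(edges))
    node_a, node_b = edge_arr[:, 0], edge_arr[:, 1]

    roles = np.zeros(n_nodes, dtype=int)
    n_io = max(1, n_nodes // 30)
    roles[np.argsort(pts[:, 0])[:n_io]] = ROLE_INLET
    roles[np.argsort(pts[:, 0])[-n_io:]] = ROLE_OUTLET
    return VascularNetwork(pts, node_a, node_b, _radii(len(node_a)),
                           wall_thickness, pore_radius, pore_fraction,
                           roles=roles)


# -- CSV I/O --------------------------------------------------------------

_NODE_COLS = ["id", "x", "y", "z", "role"]
_SEG_COLS = ["id", "node_a", "node_b", "radius", "wall_thickness",
             "pore_radius", "pore_fraction", "state"]


class NetworkParseError(ValueError):
    pass


def _paths(path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix == ".csv":
        base = base.with_suffix("")
    return (base.parent / f"{base.name}.nodes.csv",
            base.parent / f"{base.name}.segments.csv")


def write_network(network: VascularNetwork, path) -> tuple[Path, Path]:
    """Write the node/segment tables as a CSV pair ``<path>.nodes.csv`` and
    ``<path>.segments.csv``."""
    npath, spath = _paths(path)
    npath.parent.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame({
        "id": np.arange(network.n_nodes),
        "x": network.nodes[:, 0], "y": network.nodes[:, 1],
        "z": network.nodes[:, 2],
        "role": [_ROLE_NAMES[r] for r in network.roles],
    })
    segs = pd.DataFrame({
        "id": np.arange(network.n_segments),
        "node_a": network.node_a, "node_b": network.node_b,
        "radius": network.radius, "wall_thickness": network.wall_thickness,
        "pore_radius": network.pore_radius,
        "pore_fraction": network.pore_fraction,
        "state": [_STATE_NAMES[s] for s in network.state],
    })
    nodes.to_csv(npath, index=False, float_format="%.12g")
    segs.to_csv(spath, index=False, float_format="%.12g")
    return npath, spath


def read_network(path) -> VascularNetwork:
    """Read a network written by :func:`write_network` (CSV pair)."""
    npath, spath = _paths(path)
    nodes = pd.read_csv(npath)
    segs = pd.read_csv(spath)
    for df, cols, which in ((nodes, _NODE_COLS, npath), (segs, _SEG_COLS, spath)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise NetworkParseError(f"{which}: missing column(s) {missing}")
    n_nodes = len(nodes)
    for col in ("node_a", "node_b"):
        bad = segs.index[(segs[col] < 0) | (segs[col] >= n_nodes)]
        if len(bad):
            raise NetworkParseError(
                f"{spath}: line {bad[0] + 2}: segment {col} refers to a "
                "non-existent node")
    try:
        roles = np.array([_ROLE_CODES[r] for r in nodes["role"]])
        states = np.array([_STATE_CODES[s] for s in segs["state"]])
    except KeyError as exc:
        raise NetworkParseError(f"unknown role/state label {exc}") from exc
    order = np.argsort(nodes["id"].to_numpy())
    pts = nodes[["x", "y", "z"]].to_numpy()[order]
    return VascularNetwork(pts, segs["node_a"], segs["node_b"], segs["radius"],
                           segs["wall_thickness"], segs["pore_radius"],
                           segs["pore_fraction"], state=states,
                           roles=roles[order])
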