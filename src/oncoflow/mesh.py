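"""Structured hexahedral tissue mesh with a spherical tumour indicator.

The tissue block is a cube of side ``edge_length`` discretised into
``resolution``³ identical hexahedra; nodal fields live on the (n+1)³ grid
nodes.  The tumour/host indicator is a nodal mask over a central sphere whose
radius is updated by the orchestrator as the tumour grows (material
description: the indicator follows the deformed tumour boundary).
"""

from __future__ import annotations

import numpy as np


class TissueMesh:
    """Cubic structured grid.

    Attributes
    ----------
    n : int
        Elements per edge.
    edge_length : float
        Side of the cube (m).
    nodes : (N, 3) ndarray
        Node positions, C-ordered over (i, j, k) with k fastest.
    tumour_mask : (N,) bool ndarray
        True for nodes inside the tumour sphere.
    """

    def __init__(self, edge_length: float, n: int, tumour_radius: float):
        if edge_length <= 0 or tumour_radius < 0:
            raise ValueError("domain dimensions must be positive")
        if n < 4:
            raise ValueError("resolution must be at least 4 elements per edge")
        if tumour_radius >= edge_length / 2:
            raise ValueError("tumour_radius must be smaller than edge_length/2")
        self.n = int(n)
        self.edge_length = float(edge_length)
        self.h = self.edge_length / self.n
        axis = np.linspace(0.0, self.edge_length, self.n + 1)
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        self.nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        self.centre = np.full(3, self.edge_length / 2.0)
        self.radii = np.linalg.norm(self.nodes - self.centre, axis=1)
        self.tumour_radius = float(tumour_radius)
        self.fields: dict[str, np.ndarray] = {}
        # nodal integration volumes (trapezoidal weights on the grid)
        w = np.full(self.n + 1, self.h)
        w[0] = w[-1] = self.h / 2.0
        self.node_volumes = (w[:, None, None] * w[None, :, None]
                             * w[None, None, :]).ravel()
        shell = np.zeros((self.n + 1,) * 3, dtype=bool)
        shell[0, :, :] = shell[-1, :, :] = True
        shell[:, 0, :] = shell[:, -1, :] = True
        shell[:, :, 0] = shell[:, :, -1] = True
        self.boundary_mask = shell.ravel()

    # -- indexing ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return (self.n + 1) ** 3

    @property
    def n_elements(self) -> int:
        return self.n ** 3

    @property
    def element_volume(self) -> float:
        return self.h ** 3

    def node_index(self, i, j, k):
        m = self.n + 1
        return (np.asarray(i) * m + np.asarray(j)) * m + np.asarray(k)

    def grid_shape(self):
        return (self.n + 1,) * 3

    # -- tumour indicator -------------------------------------------------
    @property
    def tumour_mask(self) -> np.ndarray:
        return self.radii <= self.tumour_radius + 1e-15

    def set_tumour_radius(self, radius: float) -> None:
        if radius < 0 or radius >= self.edge_length / 2:
            raise ValueError("tumour radius outside admissible range")
        self.tumour_radius = float(radius)

    def shell_mask(self, width: float) -> np.ndarray:
        """Tumour plus a peri-tumoural shell of the given width (m)."""
        return self.radii <= self.tumour_radius + width + 1e-15

    # -- elements ---------------------------------------------------------
    def element_of_point(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Element grid index (3,) and local coordinates in [0,1]³ for a point.

        Points on the outer boundary are clipped into the last element.
        """
        p = np.asarray(p, dtype=float)
        if np.any(p < -1e-12) or np.any(p > self.edge_length + 1e-12):
            raise ValueError(f"point {p} lies outside the tissue domain")
        e = np.minimum((p / self.h).astype(int), self.n - 1)
        loc = p / self.h - e
        return e, np.clip(loc, 0.0, 1.0)

    def trilinear_weights(self, p: np.ndarray):
        """Corner node indices (8,) and trilinear weights (8,) for a point.

        Weights are a convex combination (non-negative, summing to one).
        """
        e, (u, v, w) = self.element_of_point(p)
        i, j, k = e
        corners = []
        weights = []
        for di, fu in ((0, 1 - u), (1, u)):
            for dj, fv in ((0, 1 - v), (1, v)):
                for dk, fw in ((0, 1 - w), (1, w)):
                    corners.append(self.node_index(i + di, j + dj, k + dk))
                    weights.append(fu * fv * fw)
        return np.asarray(corners), np.asarray(weights)

    def trilinear_weights_batch(self, pts: np.ndarray):
        """Vectorised corner indices (n, 8) and weights (n, 8) for points."""
        pts = np.asarray(pts, float)
        e = np.minimum((pts / self.h).astype(int), self.n - 1)
        loc = np.clip(pts / self.h - e, 0.0, 1.0)
        u, v, w = loc[:, 0], loc[:, 1], loc[:, 2]
        corners = np.empty((len(pts), 8), dtype=np.int64)
        weights = np.empty((len(pts), 8))
        c = 0
        for di, dj, dk in ((0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1),
                           (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1)):
            corners[:, c] = self.node_index(e[:, 0] + di, e[:, 1] + dj,
                                            e[:, 2] + dk)
            fu = u if di else 1 - u
            fv = v if dj else 1 - v
            fw = w if dk else 1 - w
            weights[:, c] = fu * fv * fw
            c += 1
        return corners, weights

    def gradient(self, field: np.ndarray) -> np.ndarray:
        """Central-difference nodal gradient of a nodal scalar field (per m)."""
        f = field.reshape(self.grid_shape())
        g = np.stack(np.gradient(f, self.h), axis=-1)
        return g.reshape(-1, 3)


def build_tissue_mesh(edge_length: float, resolution: int,
                      tumour_radius: float) -> TissueMesh:
    """Build the cubic tissue mesh with a central spherical tumour.

    Parameters are in metres; ``resolution`` is elements per edge (≥ 4).
    """
    return TissueMesh(edge_length, resolution, tumour_radius)
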