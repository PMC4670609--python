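"""Reference elements: shape functions and quadrature for P1/P2 tetrahedra
and their triangular boundary facets.

Node ordering follows the VTK convention: tetra corners 0-3 then mid-edge
nodes on edges (0,1), (1,2), (2,0), (0,3), (1,3), (2,3); triangle corners
0-2 then mid-edge nodes on (0,1), (1,2), (2,0).

Quadrature: linear tetrahedra carry a single barycentric point (one growth
internal variable per element); quadratic tetrahedra use the symmetric
four-point rule.  Weights are in reference-volume units (they sum to 1/6
for the tetrahedron and 1/2 for the triangle).
"""

from __future__ import annotations

import numpy as np

TET10_EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))
TRI6_EDGES = ((0, 1), (1, 2), (2, 0))

_A4 = 0.5854101966249685
_B4 = 0.1381966011250105


def tet_quadrature(order: int):
    """Return ``(points (Q,3), weights (Q,))`` for P1 (1-pt) / P2 (4-pt) tets."""
    if order == 1:
        return np.array([[0.25, 0.25, 0.25]]), np.array([1.0 / 6.0])
    if order == 2:
        pts = np.array(
            [
                [_B4, _B4, _B4],
                [_A4, _B4, _B4],
                [_B4, _A4, _B4],
                [_B4, _B4, _A4],
            ]
        )
        w = np.full(4, 1.0 / 24.0)
        return pts, w
    raise ValueError(f"unsupported element order {order}")


def tet_shape(order: int, pts: np.ndarray):
    """Shape functions ``N (Q, nn)`` and reference gradients ``dN (Q, nn, 3)``."""
    pts = np.asarray(pts, dtype=float)
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    L = np.stack([1.0 - xi - eta - zeta, xi, eta, zeta], axis=1)  # (Q,4)
    dL = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )  # (4,3)
    if order == 1:
        N = L
        dN = np.broadcast_to(dL, (pts.shape[0], 4, 3)).copy()
        return N, dN
    if order == 2:
        Q = pts.shape[0]
        N = np.empty((Q, 10))
        dN = np.empty((Q, 10, 3))
        for i in range(4):
            N[:, i] = L[:, i] * (2.0 * L[:, i] - 1.0)
            dN[:, i, :] = (4.0 * L[:, i, None] - 1.0) * dL[i]
        for m, (i, j) in enumerate(TET10_EDGES):
            N[:, 4 + m] = 4.0 * L[:, i] * L[:, j]
            dN[:, 4 + m, :] = 4.0 * (L[:, i, None] * dL[j] + L[:, j, None] * dL[i])
        return N, dN
    raise ValueError(f"unsupported element order {order}")


def tri_quadrature(order: int):
    """Facet rule: 1-pt centroid for linear, 3-pt for quadratic triangles."""
    if order == 1:
        return np.array([[1.0 / 3.0, 1.0 / 3.0]]), np.array([0.5])
    if order == 2:
        pts = np.array([[1.0 / 6.0, 1.0 / 6.0], [2.0 / 3.0, 1.0 / 6.0], [1.0 / 6.0, 2.0 / 3.0]])
        w = np.full(3, 1.0 / 6.0)
        return pts, w
    raise ValueError(f"unsupported facet order {order}")


def tri_shape(order: int, pts: np.ndarray):
    """Triangle shape functions ``N (Q, fn)`` and gradients ``dN (Q, fn, 2)``."""
    pts = np.asarray(pts, dtype=float)
    xi, eta = pts[:, 0], pts[:, 1]
    L = np.stack([1.0 - xi - eta, xi, eta], axis=1)
    dL = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    if order == 1:
        N = L
        dN = np.broadcast_to(dL, (pts.shape[0], 3, 2)).copy()
        return N, dN
    if order == 2:
        Q = pts.shape[0]
        N = np.empty((Q, 6))
        dN = np.empty((Q, 6, 2))
        for i in range(3):
            N[:, i] = L[:, i] * (2.0 * L[:, i] - 1.0)
            dN[:, i, :] = (4.0 * L[:, i, None] - 1.0) * dL[i]
        for m, (i, j) in enumerate(TRI6_EDGES):
            N[:, 3 + m] = 4.0 * L[:, i] * L[:, j]
            dN[:, 3 + m, :] = 4.0 * (L[:, i, None] * dL[j] + L[:, j, None] * dL[i])
        return N, dN
    raise ValueError(f"unsupported facet order {order}")
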