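"""Synthetic ventricular geometry, rule-based fiber architecture, and
geometric diagnostics.

The idealized left ventricle is a truncated prolate ellipsoid: the
endocardial surface is an ellipsoid of revolution with long semi-axis
``a_endo`` (apex at ``z = -a_endo``) and short semi-axis ``b_endo``; the
epicardium adds the equatorial wall thickness to the short axis and the
apical thickness to the long axis.  The wall is truncated by a flat basal
plane at ``z = truncation * a_endo``.  Construction is a structured
transfinite grid (latitudinal x circumferential x transmural) whose cells
are subdivided into tetrahedra by the translation-invariant Kuhn pattern,
which guarantees a conforming mesh with no randomness: identical parameters
give identical meshes, byte for byte.

Fiber architecture is rule-based: the helix angle rotates linearly across
the wall from ``helix_endo`` (default +60 deg) at the endocardium to
``helix_epi`` (default -60 deg) at the epicardium — the conventional
choice where no subject-specific fiber data exist — while sheets point
transmurally outward.

Diagnostics (chamber volume by the divergence theorem over the closed
deformed endocardial surface plus a flat basal cap, deformed wall volume by
quadrature, basal-ring perimeter as a crude annulus analog) operate on the
deformed configuration and are exact under rigid motions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .elements import tet_quadrature, tet_shape
from .errors import DiagnosticError, GeometryError, ParameterError
from .fibers import FiberFrame
from .mesh import VentricularMesh, promote_to_quadratic, tet_corner_volumes
from .tensors import inv3

logger = logging.getLogger(__name__)

__all__ = [
    "LVGeometryParams",
    "FiberRuleParams",
    "make_ellipsoid_lv",
    "make_box",
    "assign_fibers",
    "chamber_volume",
    "wall_volume",
    "basal_ring_perimeter",
]

MM3_PER_ML = 1000.0

#: the six Kuhn tetrahedra of a unit cell, as monotone index paths 0 -> (1,1,1)
_KUHN_PATHS = []
for _perm in itertools.permutations(range(3)):
    _corner = np.zeros(3, dtype=int)
    _path = [tuple(_corner)]
    for _ax in _perm:
        _corner = _corner.copy()
        _corner[_ax] = 1
        _path.append(tuple(_corner))
    _KUHN_PATHS.append(_path)


@dataclass(frozen=True)
class LVGeometryParams:
    """Parameters of the truncated-ellipsoid left ventricle (mm).

    a_endo, b_endo : endocardial long / short semi-axes.
    t_equator, t_apex : wall thickness at the equator / apex.
    truncation : basal plane height as a fraction of ``a_endo`` above the
        ellipsoid center (0 = truncate at the equator).
    target_edge : target element edge length controlling resolution.
    """

    a_endo: float = 45.0
    b_endo: float = 25.0
    t_equator: float = 10.0
    t_apex: float = 8.0
    truncation: float = 0.3
    target_edge: float = 7.0

    def __post_init__(self):
        for name in ("a_endo", "b_endo", "t_equator", "t_apex", "target_edge"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if not (0.0 <= self.truncation < 1.0):
            raise GeometryError("truncation must lie in [0, 1)")
        if self.t_equator >= self.b_endo:
            raise GeometryError("wall thickness must be smaller than b_endo")

    @property
    def a_epi(self) -> float:
        return self.a_endo + self.t_apex

    @property
    def b_epi(self) -> float:
        return self.b_endo + self.t_equator

    @property
    def z_base(self) -> float:
        return self.truncation * self.a_endo

    def resolution(self) -> Tuple[int, int, int]:
        """Structured grid counts (latitudinal, circumferential, transmural)
        derived from the target edge length."""
        h = self.target_edge
        b_mid = 0.5 * (self.b_endo + self.b_epi)
        a_mid = 0.5 * (self.a_endo + self.a_epi)
        n_c = max(8, int(round(2.0 * np.pi * b_mid / h)))
        phi_max = np.arccos(-self.z_base / a_mid)
        arc = phi_max * 0.5 * (a_mid + b_mid)
        n_p = max(4, int(round(arc / h)))
        n_t = max(2, int(round(self.t_equator / h)))
        return n_p, n_c, n_t


def _kuhn_tets(corner_ids: np.ndarray) -> np.ndarray:
    """Split one (possibly degenerate) hexahedral index cell into Kuhn
    tetrahedra; ``corner_ids`` is indexed ``[di, dj, dk]``."""
    tets = []
    for path in _KUHN_PATHS:
        tet = [int(corner_ids[c]) for c in path]
        if len(set(tet)) == 4:
            tets.append(tet)
    return np.array(tets, dtype=np.int64)


def make_ellipsoid_lv(
    params: LVGeometryParams,
    order: int = 2,
    resolution: Optional[Tuple[int, int, int]] = None,
) -> VentricularMesh:
    """Watertight truncated-ellipsoid LV wall, tagged
    ``{endocardium_lv, epicardium, base}``, region ``lv_wall``.

    Fully deterministic (no randomness).  ``resolution`` overrides the
    counts derived from ``target_edge``.
    """
    n_p, n_c, n_t = resolution if resolution is not None else params.resolution()
    z_base = params.z_base

    layer_size = 1 + n_p * n_c
    n_lin = (n_t + 1) * layer_size
    nodes = np.empty((n_lin, 3))
    layer_of = np.empty(n_lin, dtype=np.int64)

    def nid(k: int, ip: int, j: int) -> int:
        if ip == 0:
            return k * layer_size
        return k * layer_size + 1 + (ip - 1) * n_c + (j % n_c)

    for k in range(n_t + 1):
        s = k / n_t
        a = (1 - s) * params.a_endo + s * params.a_epi
        b = (1 - s) * params.b_endo + s * params.b_epi
        phi_max = np.arccos(-z_base / a)
        nodes[nid(k, 0, 0)] = (0.0, 0.0, -a)
        layer_of[k * layer_size : (k + 1) * layer_size] = k
        for ip in range(1, n_p + 1):
            phi = phi_max * ip / n_p
            for j in range(n_c):
                th = 2.0 * np.pi * j / n_c
                nodes[nid(k, ip, j)] = (
                    b * np.sin(phi) * np.cos(th),
                    b * np.sin(phi) * np.sin(th),
                    -a * np.cos(phi),
                )

    all_tets = []
    for k in range(n_t):
        for ip in range(n_p):
            for j in range(n_c):
                cell = np.empty((2, 2, 2), dtype=np.int64)
                for di in range(2):
                    for dj in range(2):
                        for dk in range(2):
                            cell[di, dj, dk] = nid(k + dk, ip + di, j + dj)
                all_tets.append(_kuhn_tets(cell))
    tets = np.concatenate(all_tets)

    # orient: swap last two corners of negatively oriented tets
    vols = tet_corner_volumes(nodes, tets)
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    vols = tet_corner_volumes(nodes, tets)
    scale = params.target_edge**3
    keep = vols > 1e-12 * scale
    if not np.all(keep):
        raise GeometryError("degenerate tetrahedra survived the Kuhn split")

    mesh = VentricularMesh(
        nodes=nodes,
        tets=tets,
        region_names=("lv_wall",),
        transmural=layer_of / n_t,
    )

    # boundary classification
    faces = mesh.boundary_faces()
    lay = layer_of[faces]
    ztol = 1e-8 * params.a_epi
    on_base = np.all(np.abs(nodes[faces][:, :, 2] - z_base) < ztol, axis=1)
    on_endo = np.all(lay == 0, axis=1) & ~on_base
    on_epi = np.all(lay == n_t, axis=1) & ~on_base
    unclass = ~(on_base | on_endo | on_epi)
    if np.any(unclass):
        raise GeometryError(f"{unclass.sum()} unclassified boundary faces")
    mesh.facets = {
        "endocardium_lv": faces[on_endo],
        "epicardium": faces[on_epi],
        "base": faces[on_base],
    }

    base_nodes = np.where(np.abs(nodes[:, 2] - z_base) < ztol)[0]
    ring_endo = np.array([nid(0, n_p, j) for j in range(n_c)], dtype=np.int64)
    ring_epi = np.array([nid(n_t, n_p, j) for j in range(n_c)], dtype=np.int64)
    mesh.node_sets = {
        "base": base_nodes,
        "basal_ring_endo": ring_endo,
        "basal_ring_epi": ring_epi,
    }
    if order == 2:
        mesh = promote_to_quadratic(mesh)
        base_nodes = np.where(np.abs(mesh.nodes[:, 2] - z_base) < ztol)[0]
        mesh.node_sets["base"] = base_nodes
    mesh.validate()
    return mesh


def make_box(
    lengths=(1.0, 1.0, 1.0),
    divisions=(2, 2, 2),
    order: int = 2,
) -> VentricularMesh:
    """Structured tetrahedral block with face tags ``xmin/xmax/.../zmax``.

    A testing and benchmarking geometry (patch tests, pressure checks); the
    required ventricular tags are aliased so the mesh passes validation
    (``endocardium_lv`` = ``xmin``, ``base`` = ``zmin``).
    """
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    nodes = np.array([(x, y, z) for x in xs for y in ys for z in zs])
    all_tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                cell = np.empty((2, 2, 2), dtype=np.int64)
                for di in range(2):
                    for dj in range(2):
                        for dk in range(2):
                            cell[di, dj, dk] = nid(i + di, j + dj, k + dk)
                all_tets.append(_kuhn_tets(cell))
    tets = np.concatenate(all_tets)
    vols = tet_corner_volumes(nodes, tets)
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]

    mesh = VentricularMesh(nodes=nodes, tets=tets, region_names=("lv_wall",))
    faces = mesh.boundary_faces()
    x = nodes[faces]
    tol = 1e-12 * max(lx, ly, lz)
    sets = {
        "xmin": np.all(np.abs(x[:, :, 0]) < tol, axis=1),
        "xmax": np.all(np.abs(x[:, :, 0] - lx) < tol, axis=1),
        "ymin": np.all(np.abs(x[:, :, 1]) < tol, axis=1),
        "ymax": np.all(np.abs(x[:, :, 1] - ly) < tol, axis=1),
        "zmin": np.all(np.abs(x[:, :, 2]) < tol, axis=1),
        "zmax": np.all(np.abs(x[:, :, 2] - lz) < tol, axis=1),
    }
    mesh.facets = {name: faces[m] for name, m in sets.items()}
    mesh.facets["endocardium_lv"] = mesh.facets["xmin"]
    mesh.facets["base"] = mesh.facets["zmin"]
    mesh.node_sets = {"boundary": np.unique(faces)}
    if order == 2:
        mesh = promote_to_quadratic(mesh)
        mesh.node_sets["boundary"] = np.unique(
            np.concatenate([f.ravel() for f in mesh.facets.values()])
        )
    mesh.validate()
    return mesh


@dataclass(frozen=True)
class FiberRuleParams:
    """Rule-based helix architecture: endo/epi helix angles (degrees) with
    linear transmural interpolation."""

    helix_endo_deg: float = 60.0
    helix_epi_deg: float = -60.0
    law: str = "linear"

    def __post_init__(self):
        for name in ("helix_endo_deg", "helix_epi_deg"):
            v = getattr(self, name)
            if not -90.0 <= v <= 90.0:
                raise ParameterError(f"{name} must lie in [-90, 90] degrees")
        if self.law != "linear":
            raise ParameterError("only the linear transmural law is supported")

    def helix_angle(self, s) -> np.ndarray:
        """Helix angle (radians) at transmural coordinate ``s`` in [0, 1]."""
        s = np.asarray(s, dtype=float)
        deg = self.helix_endo_deg + (self.helix_epi_deg - self.helix_endo_deg) * s
        return np.deg2rad(deg)


def transmural_coordinate(mesh: VentricularMesh) -> np.ndarray:
    """Distance-based transmural coordinate ``d_endo / (d_endo + d_epi)``
    for meshes that do not carry one (e.g. imported meshes)."""
    endo_nodes = np.unique(mesh.facets["endocardium_lv"].ravel())
    if "endocardium_rv" in mesh.facets:
        endo_nodes = np.unique(
            np.concatenate([endo_nodes, mesh.facets["endocardium_rv"].ravel()])
        )
    epi_nodes = np.unique(mesh.facets["epicardium"].ravel())
    d_endo, _ = cKDTree(mesh.nodes[endo_nodes]).query(mesh.nodes)
    d_epi, _ = cKDTree(mesh.nodes[epi_nodes]).query(mesh.nodes)
    return d_endo / np.maximum(d_endo + d_epi, 1e-30)


def assign_fibers(mesh: VentricularMesh, rule: FiberRuleParams = FiberRuleParams()) -> FiberFrame:
    """Per-element orthonormal fiber/sheet/normal frames.

    The sheet direction is the transmural gradient (endo to epi), the
    circumferential direction completes it against the long (z) axis, and
    the fiber rotates out of the circumferential plane by the helix angle of
    the element's transmural coordinate.  Degenerate elements at the apex
    pole (transmural gradient parallel to the long axis) fall back to a
    long-axis-aligned frame and are logged.
    """
    s = mesh.transmural if mesh.transmural is not None else transmural_coordinate(mesh)
    corners = mesh.tets[:, :4]
    X = mesh.nodes[corners]
    M = X[:, 1:] - X[:, :1]  # (E,3,3): rows are corner edge vectors
    d = s[corners][:, 1:] - s[corners][:, :1]
    grad_s = np.einsum("eij,ej->ei", inv3(M), d)

    g_norm = np.linalg.norm(grad_s, axis=1)
    et = grad_s / np.maximum(g_norm, 1e-30)[:, None]
    zhat = np.array([0.0, 0.0, 1.0])
    ec = np.cross(np.broadcast_to(zhat, et.shape), et)
    ec_norm = np.linalg.norm(ec, axis=1)
    degenerate = (ec_norm < 1e-6) | (g_norm < 1e-12)
    ec = ec / np.maximum(ec_norm, 1e-30)[:, None]
    el = np.cross(et, ec)

    s_bar = s[corners].mean(axis=1)
    alpha = rule.helix_angle(s_bar)
    f0 = np.cos(alpha)[:, None] * ec + np.sin(alpha)[:, None] * el
    s0 = et

    if np.any(degenerate):
        # long-axis-aligned fallback at the apex pole
        idx = np.where(degenerate)[0]
        logger.info("fiber frame fallback to long axis at %d apex elements", len(idx))
        for e in idx:
            t = et[e] if g_norm[e] > 1e-12 else zhat
            f = zhat - np.dot(zhat, t) * t
            if np.linalg.norm(f) < 1e-6:
                f = np.array([1.0, 0.0, 0.0]) - t[0] * t
            f0[e] = f / np.linalg.norm(f)
            s0[e] = t

    # numerical clean-up: exact orthonormal right-handed frames
    f0 = f0 / np.linalg.norm(f0, axis=1)[:, None]
    s0 = s0 - np.einsum("ei,ei->e", s0, f0)[:, None] * f0
    s0 = s0 / np.linalg.norm(s0, axis=1)[:, None]
    n0 = np.cross(f0, s0)
    frame = FiberFrame(f0=f0, s0=s0, n0=n0)
    frame.validate()
    return frame


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

_TRI6_SUBDIV = ((0, 3, 5), (3, 1, 4), (5, 4, 2), (3, 4, 5))


def _facet_triangles(facets: np.ndarray) -> np.ndarray:
    """Corner triangles of a facet set; quadratic facets are subdivided into
    four sub-triangles through the mid-edge nodes."""
    if facets.shape[1] == 3:
        return facets
    return np.concatenate([facets[:, list(t)] for t in _TRI6_SUBDIV])


def _flip(facets: np.ndarray) -> np.ndarray:
    if facets.shape[1] == 3:
        return facets[:, [0, 2, 1]]
    return facets[:, [0, 2, 1, 5, 4, 3]]


def chamber_volume(mesh: VentricularMesh, u=None, chamber: str = "lv") -> float:
    """Deformed chamber volume (mL) by the divergence theorem.

    The deformed endocardial surface is closed with a flat fan cap over the
    (deformed) basal ring and the volume of the resulting polyhedron is
    summed exactly.  Invariant under rigid motions.
    """
    tag = f"endocardium_{chamber}"
    ring_name = f"basal_ring_endo" if chamber == "lv" else f"basal_ring_endo_{chamber}"
    if tag not in mesh.facets:
        raise DiagnosticError(f"no facet tag {tag!r}")
    if ring_name not in mesh.node_sets:
        raise DiagnosticError(f"no ordered ring node set {ring_name!r}")
    x = mesh.nodes + mesh.displacement_view(u)

    tris = _facet_triangles(_flip(mesh.facets[tag]))  # outward of cavity
    p = x[tris]
    vol = np.einsum("fi,fi->f", np.cross(p[:, 0], p[:, 1]), p[:, 2]).sum() / 6.0

    ring = x[mesh.node_sets[ring_name]]
    c = ring.mean(axis=0)
    nxt = np.roll(ring, -1, axis=0)
    vol += np.einsum("fi,fi->f", np.cross(np.broadcast_to(c, ring.shape), ring), nxt).sum() / 6.0
    if vol <= 0:
        raise DiagnosticError("non-positive chamber volume: surface not closed/oriented")
    return vol / MM3_PER_ML


def wall_volume(mesh: VentricularMesh, u=None, region: Optional[str] = None) -> float:
    """Deformed wall volume (mL): quadrature of the deformed isoparametric
    Jacobian over the (optionally region-filtered) elements."""
    x = mesh.nodes + mesh.displacement_view(u)
    if region is None:
        tets = mesh.tets
    else:
        if region not in mesh.region_names:
            raise DiagnosticError(f"unknown region {region!r}")
        tets = mesh.tets[mesh.region_labels() == region]
    pts, w = tet_quadrature(mesh.order)
    _, dN = tet_shape(mesh.order, pts)
    J = np.einsum("eai,qaj->eqij", x[tets], dN)
    detJ = np.linalg.det(J)
    return float(np.einsum("eq,q->", detJ, w)) / MM3_PER_ML


def basal_ring_perimeter(mesh: VentricularMesh, u=None, ring: str = "endo") -> float:
    """Deformed perimeter (mm) of the ordered basal ring polyline."""
    name = f"basal_ring_{ring}"
    if name not in mesh.node_sets:
        raise DiagnosticError(f"no ordered ring node set {name!r}")
    ids = mesh.node_sets[name]
    if len(ids) < 3:
        raise DiagnosticError("ring polyline too short")
    x = (mesh.nodes + mesh.displacement_view(u))[ids]
    seg = np.roll(x, -1, axis=0) - x
    return float(np.linalg.norm(seg, axis=1).sum())
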