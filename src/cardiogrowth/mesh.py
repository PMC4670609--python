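"""Tagged tetrahedral ventricular meshes.

A :class:`VentricularMesh` is the single mesh container used throughout:
node coordinates in mm, 0-based tetrahedral connectivity (4-node linear or
10-node quadratic), named surface facet sets (``endocardium_lv``,
``epicardium``, ``base``, optionally ``endocardium_rv``), named node sets
(basal plane, ordered basal rings), and a per-element region label used to
mask growth (growth happens in ventricular wall regions only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .elements import TET10_EDGES, TRI6_EDGES
from .errors import GeometryError

__all__ = ["VentricularMesh", "tet_corner_volumes", "promote_to_quadratic"]

#: element region labels that undergo growth by default
DEFAULT_GROWTH_REGIONS = ("lv_wall", "rv_wall", "septum")


def tet_corner_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of the corner tetrahedra (first four connectivity nodes)."""
    x = nodes[tets[:, :4]]
    a = x[:, 1] - x[:, 0]
    b = x[:, 2] - x[:, 0]
    c = x[:, 3] - x[:, 0]
    return np.einsum("ei,ei->e", np.cross(a, b), c) / 6.0


@dataclass
class VentricularMesh:
    """Tagged tetrahedral mesh of a ventricular wall.

    nodes : (N, 3) coordinates in mm.
    tets : (E, 4) or (E, 10) 0-based connectivity (VTK node ordering).
    facets : tag -> (F, 3) or (F, 6) boundary triangles, oriented so the
        right-hand normal points outward from the solid.
    node_sets : name -> node index arrays; ring sets (``basal_ring_endo``,
        ``basal_ring_epi``) are ordered closed polylines.
    region : (E,) integer codes into ``region_names``.
    transmural : optional (N,) transmural coordinate (0 = endo, 1 = epi).
    """

    nodes: np.ndarray
    tets: np.ndarray
    facets: Dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    region: Optional[np.ndarray] = None
    region_names: Tuple[str, ...] = ("lv_wall",)
    transmural: Optional[np.ndarray] = None

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.region is None:
            self.region = np.zeros(self.tets.shape[0], dtype=np.int64)
        else:
            self.region = np.asarray(self.region, dtype=np.int64)

    # -- basic properties -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    @property
    def order(self) -> int:
        return 1 if self.tets.shape[1] == 4 else 2

    @property
    def n_dofs(self) -> int:
        return 3 * self.n_nodes

    def region_labels(self) -> np.ndarray:
        return np.asarray(self.region_names, dtype=object)[self.region]

    def growth_element_mask(self, growth_regions=DEFAULT_GROWTH_REGIONS) -> np.ndarray:
        codes = [i for i, n in enumerate(self.region_names) if n in growth_regions]
        return np.isin(self.region, codes)

    # -- checks -----------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`GeometryError` on inverted elements, dangling facet
        indices or missing required tags."""
        if self.tets.shape[1] not in (4, 10):
            raise GeometryError("connectivity must be 4- or 10-node tetrahedra")
        vols = tet_corner_volumes(self.nodes, self.tets)
        if np.any(vols <= 0):
            raise GeometryError(
                f"{np.sum(vols <= 0)} non-positively oriented tetrahedra"
            )
        for tag, fac in self.facets.items():
            if fac.size and fac.max() >= self.n_nodes:
                raise GeometryError(f"facet set {tag!r} references missing nodes")
        for tag in ("endocardium_lv", "base"):
            if tag not in self.facets or len(self.facets[tag]) == 0:
                raise GeometryError(f"required facet tag {tag!r} empty or missing")
        if self.region.shape[0] != self.n_elements:
            raise GeometryError("region label array length mismatch")

    def boundary_faces(self) -> np.ndarray:
        """All boundary corner-triangles (faces used by exactly one tet)."""
        corner = self.tets[:, :4]
        faces = np.concatenate(
            [
                corner[:, [1, 2, 3]],
                corner[:, [0, 3, 2]],
                corner[:, [0, 1, 3]],
                corner[:, [0, 2, 1]],
            ]
        )
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]

    def displacement_view(self, u: Optional[np.ndarray]) -> np.ndarray:
        """Accept a flat (3N,) or (N, 3) displacement; return (N, 3)."""
        if u is None:
            return np.zeros_like(self.nodes)
        u = np.asarray(u, dtype=float)
        if u.ndim == 1:
            u = u.reshape(-1, 3)
        if u.shape != self.nodes.shape:
            raise GeometryError("displacement shape does not match node array")
        return u


def promote_to_quadratic(mesh: VentricularMesh) -> VentricularMesh:
    """Convert a linear-tet mesh to 10-node quadratic tets by inserting
    mid-edge nodes (straight-edged / subparametric geometry).

    Facet sets become 6-node triangles; node sets are propagated by adding
    every midnode whose two parent nodes both belong to the set (ring sets
    keep their polyline order, interleaving midnodes).  The transmural
    coordinate is averaged onto midnodes.
    """
    if mesh.order != 1:
        raise GeometryError("mesh is already quadratic")
    tets = mesh.tets
    edges = {}
    new_nodes = [mesh.nodes]
    next_id = mesh.n_nodes

    def midnode(a: int, b: int) -> int:
        nonlocal next_id
        key = (a, b) if a < b else (b, a)
        if key not in edges:
            edges[key] = next_id
            next_id += 1
        return edges[key]

    tet10 = np.empty((mesh.n_elements, 10), dtype=np.int64)
    tet10[:, :4] = tets
    for e in range(mesh.n_elements):
        for m, (i, j) in enumerate(TET10_EDGES):
            tet10[e, 4 + m] = midnode(int(tets[e, i]), int(tets[e, j]))

    mid_xyz = np.empty((len(edges), 3))
    mid_s = np.empty(len(edges)) if mesh.transmural is not None else None
    for (a, b), nid in edges.items():
        mid_xyz[nid - mesh.n_nodes] = 0.5 * (mesh.nodes[a] + mesh.nodes[b])
        if mid_s is not None:
            mid_s[nid - mesh.n_nodes] = 0.5 * (mesh.transmural[a] + mesh.transmural[b])
    nodes = np.vstack([mesh.nodes, mid_xyz])
    transmural = (
        np.concatenate([mesh.transmural, mid_s]) if mesh.transmural is not None else None
    )

    facets = {}
    for tag, fac in mesh.facets.items():
        f6 = np.empty((fac.shape[0], 6), dtype=np.int64)
        f6[:, :3] = fac
        for k in range(fac.shape[0]):
            for m, (i, j) in enumerate(TRI6_EDGES):
                a, b = int(fac[k, i]), int(fac[k, j])
                key = (a, b) if a < b else (b, a)
                f6[k, 3 + m] = edges[key]
        facets[tag] = f6

    node_sets = {}
    for name, ids in mesh.node_sets.items():
        ids = np.asarray(ids)
        if name.startswith("basal_ring"):
            ring = []
            n = len(ids)
            for k in range(n):
                a, b = int(ids[k]), int(ids[(k + 1) % n])
                ring.append(a)
                key = (a, b) if a < b else (b, a)
                if key in edges:
                    ring.append(edges[key])
            node_sets[name] = np.array(ring, dtype=np.int64)
        else:
            members = set(int(i) for i in ids)
            extra = [nid for (a, b), nid in edges.items() if a in members and b in members]
            node_sets[name] = np.concatenate([ids, np.array(sorted(extra), dtype=np.int64)])

    return VentricularMesh(
        nodes=nodes,
        tets=tet10,
        facets=facets,
        node_sets=node_sets,
        region=mesh.region.copy(),
        region_names=mesh.region_names,
        transmural=transmural,
    )
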