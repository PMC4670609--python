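"""Mesh and field I/O: ASCII VTU output and Gmsh MSH v4.1 exchange.

VTU files are written in plain ASCII XML (UnstructuredGrid) so results can
be inspected in ParaView; MSH v4.1 is supported both ways so externally
generated ventricular meshes (physical groups mapped to the package's tag
names) can be used in place of the internal generator.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .errors import GeometryError
from .mesh import VentricularMesh

__all__ = ["write_vtu", "write_msh", "read_msh"]

_VTK_TET4 = 10
_VTK_TET10 = 24


def _fmt(arr: np.ndarray, per_line: int = 6) -> str:
    flat = np.asarray(arr).ravel()
    out = _io.StringIO()
    for i in range(0, flat.size, per_line):
        out.write(" ".join(repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v))
                           for v in flat[i : i + per_line]))
        out.write("\n")
    return out.getvalue()


def write_vtu(
    path,
    mesh: VentricularMesh,
    point_data: Optional[Dict[str, np.ndarray]] = None,
    cell_data: Optional[Dict[str, np.ndarray]] = None,
) -> None:
    """Write the mesh and optional nodal/cell fields as ASCII VTU."""
    point_data = point_data or {}
    cell_data = cell_data or {}
    n_pts, n_cells = mesh.n_nodes, mesh.n_elements
    nn = mesh.tets.shape[1]
    ctype = _VTK_TET4 if nn == 4 else _VTK_TET10

    def data_arrays(data: Dict[str, np.ndarray], n: int) -> str:
        parts = []
        for name, arr in data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            if arr.shape[0] != n:
                raise GeometryError(f"field {name!r} has wrong length")
            parts.append(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n'
                + _fmt(arr.astype(float))
                + "</DataArray>\n"
            )
        return "".join(parts)

    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        fh.write("<UnstructuredGrid>\n")
        fh.write(f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">\n')
        fh.write("<Points>\n")
        fh.write('<DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        fh.write(_fmt(mesh.nodes))
        fh.write("</DataArray>\n</Points>\n")
        fh.write("<Cells>\n")
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        fh.write(_fmt(mesh.tets, per_line=nn))
        fh.write("</DataArray>\n")
        fh.write('<DataArray type="Int64" Name="offsets" format="ascii">\n')
        fh.write(_fmt(np.arange(1, n_cells + 1) * nn, per_line=12))
        fh.write("</DataArray>\n")
        fh.write('<DataArray type="Int64" Name="types" format="ascii">\n')
        fh.write(_fmt(np.full(n_cells, ctype), per_line=20))
        fh.write("</DataArray>\n</Cells>\n")
        fh.write("<PointData>\n" + data_arrays(point_data, n_pts) + "</PointData>\n")
        fh.write("<CellData>\n" + data_arrays(cell_data, n_cells) + "</CellData>\n")
        fh.write("</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")


# ---------------------------------------------------------------------------
# Gmsh MSH v4.1 (ASCII)
# ---------------------------------------------------------------------------

_MSH_TRI3, _MSH_TRI6 = 2, 9
_MSH_TET4, _MSH_TET10 = 4, 11

# Gmsh tet10 edge-node ordering differs from VTK in the last two midnodes:
# gmsh edges are (0,1),(1,2),(2,0),(0,3),(2,3),(1,3); VTK uses (0,3),(1,3),(2,3).
_GMSH_FROM_VTK_TET10 = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]
_VTK_FROM_GMSH_TET10 = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]


def write_msh(path, mesh: VentricularMesh) -> None:
    """Write MSH v4.1: one discrete surface entity per facet tag, one volume
    entity per region, with matching physical names (1-based node ids)."""
    surf_tags = sorted(mesh.facets)
    vol_names = list(mesh.region_names)
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        fh.write("$PhysicalNames\n")
        fh.write(f"{len(surf_tags) + len(vol_names)}\n")
        for i, tag in enumerate(surf_tags):
            fh.write(f'2 {i + 1} "{tag}"\n')
        for i, name in enumerate(vol_names):
            fh.write(f'3 {100 + i + 1} "{name}"\n')
        fh.write("$EndPhysicalNames\n")
        lo = mesh.nodes.min(axis=0)
        hi = mesh.nodes.max(axis=0)
        box = f"{lo[0]} {lo[1]} {lo[2]} {hi[0]} {hi[1]} {hi[2]}"
        fh.write("$Entities\n")
        fh.write(f"0 0 {len(surf_tags)} {len(vol_names)}\n")
        for i in range(len(surf_tags)):
            fh.write(f"{i + 1} {box} 1 {i + 1} 0\n")
        for i in range(len(vol_names)):
            fh.write(f"{100 + i + 1} {box} 1 {100 + i + 1} 0\n")
        fh.write("$EndEntities\n")
        # single node block on the first volume entity
        n = mesh.n_nodes
        fh.write("$Nodes\n")
        fh.write(f"1 {n} 1 {n}\n")
        fh.write(f"3 101 0 {n}\n")
        for i in range(n):
            fh.write(f"{i + 1}\n")
        for x in mesh.nodes:
            fh.write(f"{float(x[0])!r} {float(x[1])!r} {float(x[2])!r}\n")
        fh.write("$EndNodes\n")

        nn = mesh.tets.shape[1]
        tet_type = _MSH_TET4 if nn == 4 else _MSH_TET10
        blocks = []
        for i, tag in enumerate(surf_tags):
            fac = mesh.facets[tag]
            ftype = _MSH_TRI3 if fac.shape[1] == 3 else _MSH_TRI6
            blocks.append((2, i + 1, ftype, fac))
        for i, name in enumerate(vol_names):
            els = mesh.tets[mesh.region == i]
            if nn == 10:
                els = els[:, _GMSH_FROM_VTK_TET10]
            blocks.append((3, 100 + i + 1, tet_type, els))
        blocks = [b for b in blocks if len(b[3])]
        n_el = sum(len(b[3]) for b in blocks)
        fh.write("$Elements\n")
        fh.write(f"{len(blocks)} {n_el} 1 {n_el}\n")
        eid = 1
        for dim, ent, etype, conn in blocks:
            fh.write(f"{dim} {ent} {etype} {len(conn)}\n")
            for row in conn:
                fh.write(str(eid) + " " + " ".join(str(int(v) + 1) for v in row) + "\n")
                eid += 1
        fh.write("$EndElements\n")


def read_msh(path) -> VentricularMesh:
    """Read an ASCII MSH v4.1 mesh with tets/triangles and physical names.

    Physical surface names become facet tags; physical volume names become
    region labels.  Node ids are compacted to a 0-based contiguous range.
    """
    text = Path(path).read_text().splitlines()
    sections: Dict[str, list] = {}
    name = None
    for line in text:
        s = line.strip()
        if s.startswith("$End"):
            name = None
        elif s.startswith("$"):
            name = s[1:]
            sections[name] = []
        elif name is not None:
            sections[name].append(s)
    if "MeshFormat" not in sections or not sections["MeshFormat"][0].startswith("4.1"):
        raise GeometryError("only ASCII MSH v4.1 is supported")

    phys = {}  # (dim, tag) -> name
    if "PhysicalNames" in sections:
        for line in sections["PhysicalNames"][1:]:
            parts = line.split(maxsplit=2)
            phys[(int(parts[0]), int(parts[1]))] = parts[2].strip('"')

    ent_phys = {}  # (dim, entity) -> physical tag
    if "Entities" in sections:
        counts = [int(v) for v in sections["Entities"][0].split()]
        idx = 1
        for dim, cnt in enumerate(counts):
            for _ in range(cnt):
                parts = sections["Entities"][idx].split()
                idx += 1
                tag = int(parts[0])
                nbox = 3 if dim == 0 else 6
                nphys = int(parts[1 + nbox])
                if nphys > 0:
                    ent_phys[(dim, tag)] = int(parts[2 + nbox])

    lines = sections["Nodes"]
    n_blocks = int(lines[0].split()[0])
    ids, coords = [], []
    li = 1
    for _ in range(n_blocks):
        _, _, _, n_in = (int(v) for v in lines[li].split())
        li += 1
        blk_ids = [int(lines[li + i]) for i in range(n_in)]
        li += n_in
        for i in range(n_in):
            coords.append([float(v) for v in lines[li + i].split()[:3]])
        li += n_in
        ids.extend(blk_ids)
    id_map = {gid: k for k, gid in enumerate(ids)}
    nodes = np.asarray(coords)

    lines = sections["Elements"]
    n_blocks = int(lines[0].split()[0])
    li = 1
    facets: Dict[str, list] = {}
    tets, tet_names = [], []
    for _ in range(n_blocks):
        dim, ent, etype, n_in = (int(v) for v in lines[li].split())
        li += 1
        conn = []
        for i in range(n_in):
            parts = lines[li + i].split()
            conn.append([id_map[int(v)] for v in parts[1:]])
        li += n_in
        pname = phys.get((dim, ent_phys.get((dim, ent), -1)))
        if etype in (_MSH_TRI3, _MSH_TRI6):
            if pname:
                facets.setdefault(pname, []).extend(conn)
        elif etype in (_MSH_TET4, _MSH_TET10):
            arr = np.asarray(conn, dtype=np.int64)
            if etype == _MSH_TET10:
                arr = arr[:, _VTK_FROM_GMSH_TET10]
            tets.append(arr)
            tet_names.extend([pname or "lv_wall"] * len(arr))
    if not tets:
        raise GeometryError("no tetrahedra found in MSH file")
    tets = np.concatenate(tets)
    region_names = tuple(dict.fromkeys(tet_names))
    region = np.array([region_names.index(n) for n in tet_names], dtype=np.int64)

    mesh = VentricularMesh(
        nodes=nodes,
        tets=tets,
        facets={k: np.asarray(v, dtype=np.int64) for k, v in facets.items()},
        region=region,
        region_names=region_names,
    )
    return mesh
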