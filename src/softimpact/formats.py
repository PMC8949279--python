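"""Mesh file formats: a Gmsh MSH 4.1 subset and VTK XML unstructured grids.

Only what the package needs is implemented:

* MSH 4.1 (ASCII): nodes, tetrahedra (type 4) grouped into one volume entity
  per material tag, and node sets encoded as 1-node point elements (type 15)
  on point entities; physical names carry set/material identities.  Files are
  1-based on disk, 0-based in memory.
* VTU (XML, ASCII): points, tet cells, node sets as 0/1 integer point-data
  arrays named ``nodeset:<name>``, material tags as cell data
  ``material_tag``.  Arbitrary point-data fields (e.g. acceleration
  magnitudes) can be attached, plus a ParaView ``.pvd`` collection index for
  time series.

Round-trips preserve coordinates to machine precision (17 significant
digits) and connectivity exactly.  Non-tetrahedral cells are skipped with a
warning; malformed records raise :class:`MeshParseError` naming the
offending location.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import Mesh

__all__ = [
    "MeshParseError",
    "read_msh",
    "write_msh",
    "read_vtu",
    "write_vtu",
    "write_vtu_fields",
    "write_pvd",
]

VTK_TET = 10
MSH_TET = 4
MSH_POINT = 15
#: nodes per Gmsh element type, for the types we can at least skip over
_MSH_NODES_PER_TYPE = {1: 2, 2: 3, 3: 4, 4: 4, 5: 8, 6: 6, 7: 5, 15: 1}


class MeshParseError(ValueError):
    """Malformed mesh file."""


# ---------------------------------------------------------------------------
# MSH 4.1
# ---------------------------------------------------------------------------

def write_msh(mesh: Mesh, path) -> None:
    mesh.validate()
    tags = np.unique(mesh.element_tags)
    set_names = sorted(mesh.node_sets)
    lines: list[str] = []
    lines += ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]

    # physical names: dim 0 for node sets, dim 3 for materials
    lines.append("$PhysicalNames")
    lines.append(str(len(set_names) + len(tags)))
    point_phys = {}
    vol_phys = {}
    phys = 1
    for name in set_names:
        point_phys[name] = phys
        lines.append(f'0 {phys} "nodeset:{name}"')
        phys += 1
    for t in tags:
        vol_phys[int(t)] = phys
        lines.append(f'3 {phys} "material:{int(t)}"')
        phys += 1
    lines.append("$EndPhysicalNames")

    lines.append("$Entities")
    lines.append(f"{len(set_names)} 0 0 {len(tags)}")
    point_ent = {}
    for i, name in enumerate(set_names, start=1):
        point_ent[name] = i
        lines.append(f"{i} 0 0 0 1 {point_phys[name]}")
    lo = mesh.nodes.min(axis=0) if mesh.n_nodes else np.zeros(3)
    hi = mesh.nodes.max(axis=0) if mesh.n_nodes else np.zeros(3)
    vol_ent = {}
    for i, t in enumerate(tags, start=1):
        vol_ent[int(t)] = i
        bbox = " ".join(f"{v:.17g}" for v in (*lo, *hi))
        lines.append(f"{i} {bbox} 1 {vol_phys[int(t)]} 0")
    lines.append("$EndEntities")

    lines.append("$Nodes")
    n = mesh.n_nodes
    lines.append(f"1 {n} 1 {n}")
    lines.append(f"3 {vol_ent[int(tags[0])]} 0 {n}")
    lines += [str(i) for i in range(1, n + 1)]
    lines += [" ".join(f"{c:.17g}" for c in p) for p in mesh.nodes]
    lines.append("$EndNodes")

    # one block per contiguous run of equal tags, so element order round-trips
    runs = []
    for e, t in enumerate(mesh.element_tags):
        if runs and runs[-1][0] == t:
            runs[-1][1].append(e)
        else:
            runs.append((int(t), [e]))
    lines.append("$Elements")
    n_elem = mesh.n_elements + sum(len(v) for v in mesh.node_sets.values())
    n_blocks = len(runs) + sum(1 for name in set_names if len(mesh.node_sets[name]))
    lines.append(f"{n_blocks} {n_elem} 1 {n_elem}")
    eid = 1
    for t, idx in runs:
        lines.append(f"3 {vol_ent[t]} {MSH_TET} {len(idx)}")
        for e in idx:
            conn = " ".join(str(int(v) + 1) for v in mesh.tets[e])
            lines.append(f"{eid} {conn}")
            eid += 1
    for name in set_names:
        ids = mesh.node_sets[name]
        if not len(ids):
            continue
        lines.append(f"0 {point_ent[name]} {MSH_POINT} {len(ids)}")
        for v in ids:
            lines.append(f"{eid} {int(v) + 1}")
            eid += 1
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")


def _msh_sections(text: str, path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("$End"):
            current = None
        elif line.startswith("$"):
            current = line[1:]
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
        else:
            raise MeshParseError(f"{path}: stray data outside any section at line {ln}")
    return sections


def read_msh(path) -> Mesh:
    text = Path(path).read_text()
    sec = _msh_sections(text, path)
    if "MeshFormat" not in sec or "Nodes" not in sec or "Elements" not in sec:
        raise MeshParseError(f"{path}: missing MeshFormat/Nodes/Elements section")
    version = sec["MeshFormat"][0].split()[0]
    if not version.startswith("4."):
        raise MeshParseError(f"{path}: unsupported MSH version {version} (need 4.x)")

    phys_names: dict[tuple[int, int], str] = {}
    for line in sec.get("PhysicalNames", [])[1:]:
        parts = line.split(maxsplit=2)
        phys_names[(int(parts[0]), int(parts[1]))] = parts[2].strip('"')

    # entity -> physical tag, for dims 0 and 3
    ent_phys: dict[tuple[int, int], int] = {}
    ent_lines = sec.get("Entities", [])
    if ent_lines:
        counts = [int(v) for v in ent_lines[0].split()]
        if len(counts) != 4:
            raise MeshParseError(f"{path}: malformed $Entities header")
        rows = ent_lines[1:]
        pos = 0
        for dim, cnt in zip((0, 1, 2, 3), counts):
            for _ in range(cnt):
                parts = rows[pos].split()
                pos += 1
                tag = int(parts[0])
                n_coord = 3 if dim == 0 else 6
                n_phys = int(parts[1 + n_coord])
                if n_phys:
                    ent_phys[(dim, tag)] = int(parts[2 + n_coord])

    # nodes
    rows = sec["Nodes"]
    n_blocks, n_nodes = (int(v) for v in rows[0].split()[:2])
    pos = 1
    tag_to_idx: dict[int, int] = {}
    coords = np.empty((n_nodes, 3))
    filled = 0
    for _ in range(n_blocks):
        _, _, _, n_in = (int(v) for v in rows[pos].split())
        pos += 1
        tags = [int(rows[pos + i]) for i in range(n_in)]
        pos += n_in
        for i, t in enumerate(tags):
            parts = rows[pos + i].split()
            if len(parts) < 3:
                raise MeshParseError(f"{path}: node {t} has fewer than 3 coordinates")
            tag_to_idx[t] = filled + i
            coords[filled + i] = [float(v) for v in parts[:3]]
        pos += n_in
        filled += n_in

    # elements
    rows = sec["Elements"]
    n_blocks = int(rows[0].split()[0])
    pos = 1
    tets: list[list[int]] = []
    tet_tags: list[int] = []
    node_sets: dict[str, list[int]] = {}
    skipped = 0
    for _ in range(n_blocks):
        dim, ent, etype, n_in = (int(v) for v in rows[pos].split())
        pos += 1
        if etype not in _MSH_NODES_PER_TYPE:
            raise MeshParseError(f"{path}: unknown element type {etype}")
        nn = _MSH_NODES_PER_TYPE[etype]
        for i in range(n_in):
            parts = rows[pos + i].split()
            if len(parts) != nn + 1:
                raise MeshParseError(
                    f"{path}: element record '{rows[pos + i]}' has {len(parts) - 1} "
                    f"nodes, expected {nn} for type {etype}"
                )
            if etype == MSH_TET:
                tets.append([tag_to_idx[int(v)] for v in parts[1:]])
                phys = ent_phys.get((3, ent))
                name = phys_names.get((3, phys), "") if phys is not None else ""
                mat = int(name.split(":")[1]) if name.startswith("material:") else 1
                tet_tags.append(mat)
            elif etype == MSH_POINT:
                phys = ent_phys.get((0, ent))
                name = phys_names.get((0, phys), "") if phys is not None else ""
                if name.startswith("nodeset:"):
                    node_sets.setdefault(name.split(":", 1)[1], []).append(
                        tag_to_idx[int(parts[1])]
                    )
            else:
                skipped += 1
        pos += n_in
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} non-tetrahedral cells", stacklevel=2)
    return Mesh(
        coords,
        np.asarray(tets, dtype=np.int64).reshape(-1, 4),
        {k: np.asarray(v) for k, v in node_sets.items()},
        np.asarray(tet_tags, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# VTU
# ---------------------------------------------------------------------------

def _data_array(parent, name, values, vtype, ncomp=1) -> None:
    el = ET.SubElement(parent, "DataArray", type=vtype, Name=name, format="ascii")
    if ncomp != 1:
        el.set("NumberOfComponents", str(ncomp))
    arr = np.asarray(values)
    if arr.dtype.kind == "f":
        el.text = " ".join(f"{v:.17g}" for v in arr.ravel())
    else:
        el.text = " ".join(str(int(v)) for v in arr.ravel())


def write_vtu(mesh: Mesh, path) -> None:
    point_data = {
        f"nodeset:{name}": np.isin(np.arange(mesh.n_nodes), ids).astype(np.int64)
        for name, ids in mesh.node_sets.items()
    }
    write_vtu_fields(path, mesh.nodes, mesh.tets, point_data=point_data,
                     cell_data={"material_tag": mesh.element_tags})


def write_vtu_fields(path, nodes, tets, point_data=None, cell_data=None) -> None:
    """Write a tet mesh plus arbitrary scalar point/cell data as ASCII VTU."""
    nodes = np.asarray(nodes, dtype=float)
    tets = np.asarray(tets, dtype=np.int64)
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="1.0",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(len(nodes)),
                          NumberOfCells=str(len(tets)))
    pts = ET.SubElement(piece, "Points")
    _data_array(pts, "Points", nodes, "Float64", ncomp=3)
    cells = ET.SubElement(piece, "Cells")
    _data_array(cells, "connectivity", tets, "Int64")
    _data_array(cells, "offsets", 4 * np.arange(1, len(tets) + 1), "Int64")
    _data_array(cells, "types", np.full(len(tets), VTK_TET), "UInt8")
    if point_data:
        pd = ET.SubElement(piece, "PointData")
        for name, vals in point_data.items():
            arr = np.asarray(vals)
            _data_array(pd, name, arr, "Float64" if arr.dtype.kind == "f" else "Int64")
    if cell_data:
        cd = ET.SubElement(piece, "CellData")
        for name, vals in cell_data.items():
            arr = np.asarray(vals)
            _data_array(cd, name, arr, "Float64" if arr.dtype.kind == "f" else "Int64")
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="UTF-8")


def _find_array(piece, name):
    for da in piece.iter("DataArray"):
        if da.get("Name") == name:
            return da
    return None


def _parse_array(da, dtype, path, name):
    try:
        text = da.text or ""
        return np.array(text.split(), dtype=dtype)
    except ValueError as exc:
        raise MeshParseError(f"{path}: cannot parse DataArray {name!r}: {exc}") from exc


def read_vtu(path):
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise MeshParseError(f"{path}: not well-formed XML: {exc}") from exc
    piece = tree.getroot().find(".//Piece")
    if piece is None:
        raise MeshParseError(f"{path}: no <Piece> element")
    pts = _find_array(piece.find("Points"), "Points")
    if pts is None:
        raise MeshParseError(f"{path}: missing Points array")
    nodes = _parse_array(pts, float, path, "Points").reshape(-1, 3)

    cells = piece.find("Cells")
    conn = _parse_array(_find_array(cells, "connectivity"), np.int64, path, "connectivity")
    offsets = _parse_array(_find_array(cells, "offsets"), np.int64, path, "offsets")
    types = _parse_array(_find_array(cells, "types"), np.int64, path, "types")
    if len(offsets) != len(types):
        raise MeshParseError(f"{path}: offsets/types length mismatch")

    tets, keep_cells = [], []
    starts = np.concatenate([[0], offsets[:-1]])
    skipped = 0
    for i, (s, e, t) in enumerate(zip(starts, offsets, types)):
        if t == VTK_TET:
            if e - s != 4:
                raise MeshParseError(f"{path}: tet cell {i} has {e - s} nodes")
            tets.append(conn[s:e])
            keep_cells.append(i)
        else:
            skipped += 1
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} non-tetrahedral cells", stacklevel=2)
    tets = np.asarray(tets, dtype=np.int64).reshape(-1, 4)

    node_sets = {}
    pd = piece.find("PointData")
    if pd is not None:
        for da in pd.iter("DataArray"):
            name = da.get("Name", "")
            if name.startswith("nodeset:"):
                flags = _parse_array(da, np.int64, path, name)
                node_sets[name.split(":", 1)[1]] = np.flatnonzero(flags)

    tags = None
    cd = piece.find("CellData")
    if cd is not None:
        da = _find_array(cd, "material_tag")
        if da is not None:
            tags = _parse_array(da, np.int64, path, "material_tag")[keep_cells]
    return Mesh(nodes, tets, node_sets, tags)


def write_pvd(path, entries) -> None:
    """ParaView collection index: entries is a list of (time, filename)."""
    root = ET.Element("VTKFile", type="Collection", version="1.0")
    coll = ET.SubElement(root, "Collection")
    for t, fname in entries:
        ET.SubElement(coll, "DataSet", timestep=f"{t:.17g}", part="0", file=str(fname))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="UTF-8")
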