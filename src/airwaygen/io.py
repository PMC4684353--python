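"""File exchange for centreline trees and lobar surfaces.

Two tree dialects, both lossless for positions, radii, topology, origin tags
and lobe labels (mm units):

* legacy VTK ASCII polydata (``.vtk``): POINTS + one LINES polyline per
  branch, a point-data scalar array ``radius`` and cell-data arrays ``origin``
  (0 = ct, 1 = generated) and ``lobe`` (0 = none, then RUL, RML, RLL, LUL,
  LLL).  The first point written is the tree inlet (trachea entrance), which
  is how the root is recovered on read.
* CSV pair: ``nodes.csv`` (id,x,y,z,radius) and ``edges.csv``
  (parent_node,child_node[,origin,lobe]), header row, 0-based ids; the inlet
  is the node that never appears as a child.

Surfaces load through trimesh (STL/OFF/PLY) and are validated watertight.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import trimesh

from .core import (
    AirwayTree,
    GeometryError,
    LobeSurface,
    LOBE_LABELS,
    TreeStructureError,
    build_branches_from_centreline,
)

__all__ = ["read_tree", "write_tree", "read_surface", "write_surface",
           "ParseError"]

_LOBE_CODE = {None: 0, "none": 0, **{lab: i + 1 for i, lab in enumerate(LOBE_LABELS)}}
_CODE_LOBE = {0: None, **{i + 1: lab for i, lab in enumerate(LOBE_LABELS)}}


class ParseError(ValueError):
    pass


def _fmt(x: float) -> str:
    return format(float(x), ".9g")


# ---------------------------------------------------------------------------
# VTK legacy ASCII polydata
# ---------------------------------------------------------------------------

def _write_vtk(tree: AirwayTree, path: Path) -> None:
    order = tree.branches_preorder()
    node_index: Dict[int, int] = {}
    coords, radii = [], []
    for bid in order:  # root branch first, so point 0 is the inlet
        for nid in tree.branches[bid].node_path:
            if nid not in node_index:
                node_index[nid] = len(coords)
                coords.append(tree.nodes[nid].position)
                radii.append(tree.nodes[nid].radius)
    lines = []
    for bid in order:
        path_idx = [node_index[n] for n in tree.branches[bid].node_path]
        lines.append(path_idx)

    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("airway centreline tree\n")
        f.write("ASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {len(coords)} float\n")
        for p in coords:
            f.write(f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")
        total = sum(len(li) + 1 for li in lines)
        f.write(f"LINES {len(lines)} {total}\n")
        for li in lines:
            f.write(" ".join([str(len(li))] + [str(i) for i in li]) + "\n")
        f.write(f"POINT_DATA {len(coords)}\n")
        f.write("SCALARS radius float 1\nLOOKUP_TABLE default\n")
        for r in radii:
            f.write(_fmt(r) + "\n")
        f.write(f"CELL_DATA {len(lines)}\n")
        f.write("SCALARS origin int 1\nLOOKUP_TABLE default\n")
        for bid in order:
            f.write(f"{0 if tree.branches[bid].origin == 'ct' else 1}\n")
        f.write("SCALARS lobe int 1\nLOOKUP_TABLE default\n")
        for bid in order:
            f.write(f"{_LOBE_CODE[tree.branches[bid].lobe]}\n")


def _read_vtk(path: Path) -> AirwayTree:
    tokens = []
    with open(path) as f:
        lines = f.readlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise ParseError(f"{path}: not a legacy VTK file (bad header)")
    if lines[2].strip().upper() != "ASCII":
        raise ParseError(f"{path}: only ASCII legacy VTK is supported")
    for ln in lines[4:]:
        tokens.extend(ln.split())
    pos = 0

    def take(n):
        nonlocal pos
        out = tokens[pos:pos + n]
        if len(out) < n:
            raise ParseError(f"{path}: truncated file near token {pos}")
        pos += n
        return out

    points = None
    polylines = []
    radius = None
    origin_codes = None
    lobe_codes = None
    section = "POINT_DATA"
    while pos < len(tokens):
        key = tokens[pos].upper()
        if key == "POINTS":
            n = int(tokens[pos + 1]); pos += 3
            vals = np.array(take(3 * n), dtype=float)
            points = vals.reshape(n, 3)
        elif key == "LINES":
            n_lines = int(tokens[pos + 1]); pos += 3
            for _ in range(n_lines):
                k = int(take(1)[0])
                polylines.append([int(t) for t in take(k)])
        elif key in ("POINT_DATA", "CELL_DATA"):
            section = key
            pos += 2
        elif key == "SCALARS":
            name = tokens[pos + 1].lower()
            pos += 3  # SCALARS name type
            if pos < len(tokens) and tokens[pos].isdigit():
                pos += 1  # optional component count
            if pos < len(tokens) and tokens[pos].upper() == "LOOKUP_TABLE":
                pos += 2
            count = len(points) if section == "POINT_DATA" else len(polylines)
            vals = take(count)
            if name == "radius":
                radius = np.array(vals, dtype=float)
            elif name == "origin":
                origin_codes = np.array(vals, dtype=int)
            elif name == "lobe":
                lobe_codes = np.array(vals, dtype=int)
        else:
            pos += 1
    if points is None or not polylines:
        raise ParseError(f"{path}: missing POINTS or LINES section")
    if radius is None:
        raise ParseError(f"{path}: missing point-data scalar array 'radius'")

    nodes = [(i, points[i], radius[i]) for i in range(len(points))]
    edges, origins, lobes = [], {}, {}
    for ci, pl in enumerate(polylines):
        o = "generated" if origin_codes is not None and origin_codes[ci] else "ct"
        lb = _CODE_LOBE.get(int(lobe_codes[ci])) if lobe_codes is not None else None
        for a, b in zip(pl[:-1], pl[1:]):
            edges.append((a, b))
        origins[(pl[0], pl[1])] = o
        lobes[(pl[0], pl[1])] = lb
    return build_branches_from_centreline(nodes, edges, root_node=0,
                                          origins=origins, lobes=lobes)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _csv_paths(path: Path) -> Tuple[Path, Path]:
    if path.is_dir():
        return path / "nodes.csv", path / "edges.csv"
    name = path.name
    if "nodes" in name:
        return path, path.with_name(name.replace("nodes", "edges"))
    if "edges" in name:
        return path.with_name(name.replace("edges", "nodes")), path
    raise ParseError(
        f"{path}: CSV trees need a nodes.csv/edges.csv pair (pass the "
        "directory or either file)")


def _write_csv(tree: AirwayTree, path: Path) -> None:
    nodes_path, edges_path = _csv_paths(path)
    nodes_path.parent.mkdir(parents=True, exist_ok=True)
    order = tree.branches_preorder()
    node_ids: Dict[int, int] = {}
    with open(nodes_path, "w") as f:
        f.write("id,x,y,z,radius\n")
        for bid in order:
            for nid in tree.branches[bid].node_path:
                if nid in node_ids:
                    continue
                node_ids[nid] = len(node_ids)
                nd = tree.nodes[nid]
                f.write(f"{node_ids[nid]},{_fmt(nd.position[0])},"
                        f"{_fmt(nd.position[1])},{_fmt(nd.position[2])},"
                        f"{_fmt(nd.radius)}\n")
    with open(edges_path, "w") as f:
        f.write("parent_node,child_node,origin,lobe\n")
        for bid in order:
            br = tree.branches[bid]
            for a, b in zip(br.node_path[:-1], br.node_path[1:]):
                f.write(f"{node_ids[a]},{node_ids[b]},{br.origin},"
                        f"{br.lobe or 'none'}\n")


def _read_csv(path: Path) -> AirwayTree:
    nodes_path, edges_path = _csv_paths(path)
    for p in (nodes_path, edges_path):
        if not p.exists():
            raise ParseError(f"missing file {p}")

    with open(nodes_path) as f:
        header = f.readline().strip().split(",")
        required = ["id", "x", "y", "z", "radius"]
        for col in required:
            if col not in header:
                raise ParseError(f"{nodes_path}: missing column '{col}'")
        col = {c: header.index(c) for c in required}
        nodes = []
        for i, ln in enumerate(f, start=2):
            if not ln.strip():
                continue
            parts = ln.strip().split(",")
            try:
                nodes.append((int(parts[col["id"]]),
                              [float(parts[col["x"]]), float(parts[col["y"]]),
                               float(parts[col["z"]])],
                              float(parts[col["radius"]])))
            except (ValueError, IndexError) as e:
                raise ParseError(f"{nodes_path}:{i}: {e}") from None

    with open(edges_path) as f:
        header = f.readline().strip().split(",")
        for colname in ("parent_node", "child_node"):
            if colname not in header:
                raise ParseError(f"{edges_path}: missing column '{colname}'")
        ip = header.index("parent_node")
        ic = header.index("child_node")
        io_ = header.index("origin") if "origin" in header else None
        il = header.index("lobe") if "lobe" in header else None
        edges, origins, lobes = [], {}, {}
        for i, ln in enumerate(f, start=2):
            if not ln.strip():
                continue
            parts = ln.strip().split(",")
            try:
                a, b = int(parts[ip]), int(parts[ic])
            except (ValueError, IndexError) as e:
                raise ParseError(f"{edges_path}:{i}: {e}") from None
            edges.append((a, b))
            if io_ is not None:
                origins[(a, b)] = parts[io_]
            if il is not None:
                lobes[(a, b)] = None if parts[il] == "none" else parts[il]

    # propagate edge tags branch-wise: build first, tags come from first edge
    tree = build_branches_from_centreline(nodes, edges,
                                          origins=origins, lobes=lobes)
    return tree


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_tree(path: Union[str, Path]) -> AirwayTree:
    path = Path(path)
    if path.is_dir() or path.suffix.lower() == ".csv":
        tree = _read_csv(path)
    elif path.suffix.lower() == ".vtk":
        tree = _read_vtk(path)
    else:
        raise ParseError(f"{path}: unsupported tree format (use .vtk or CSV pair)")
    # a generated branch has one assigned diameter, carried by the nodes it
    # owns (every path node after the junction shared with its parent)
    for br in tree.branches.values():
        if br.origin == "generated":
            br.diameter = 2.0 * tree.nodes[br.node_path[-1]].radius
    return tree


def write_tree(tree: AirwayTree, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.is_dir() or path.suffix.lower() == ".csv":
        _write_csv(tree, path)
    elif path.suffix.lower() == ".vtk":
        path.parent.mkdir(parents=True, exist_ok=True)
        _write_vtk(tree, path)
    else:
        raise ParseError(f"{path}: unsupported tree format (use .vtk or CSV pair)")


def read_surface(path: Union[str, Path], label: Optional[str] = None
                 ) -> LobeSurface:
    path = Path(path)
    mesh = trimesh.load(str(path), force="mesh", process=False)
    mesh.merge_vertices()  # STL stores a triangle soup
    if label is None:
        stem = path.stem.upper()
        label = next((lab for lab in LOBE_LABELS if lab in stem), path.stem)
    surf = LobeSurface(np.asarray(mesh.vertices, float),
                       np.asarray(mesh.faces, np.int64), label=label)
    surf.validate()
    return surf


def write_surface(surface: LobeSurface, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    surface.mesh.export(str(path))


def tree_bytes(tree: AirwayTree) -> bytes:
    """Canonical byte serialisation of a tree (the VTK dialect), for
    determinism checks and manifest hashing."""
    import tempfile
    with tempfile.TemporaryDirectory() as td:
        p = Path(td) / "tree.vtk"
        _write_vtk(tree, p)
        return p.read_bytes()
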