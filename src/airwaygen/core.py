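"""Centreline airway-tree data model and the ordering/geometry primitives.

An airway tree is a rooted, strictly bifurcating tree of *branches*.  Each
branch is a polyline of centreline nodes (proximal to distal) carrying a
per-point lumen radius, and is tagged with its provenance: ``ct`` for branches
measured from imaging-derived centrelines, ``generated`` for branches created
by the volume-filling growth algorithm.  Host volumes (lung lobes) are closed
triangulated surfaces.

All file-level geometry is in millimetres; conversion to SI happens only in
the resistance module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import trimesh

LOBE_LABELS = ("RUL", "RML", "RLL", "LUL", "LLL")

__all__ = [
    "Node",
    "Branch",
    "AirwayTree",
    "LobeSurface",
    "TreeStructureError",
    "GeometryError",
    "build_branches_from_centreline",
    "assign_generations",
    "assign_horsfield_orders",
    "assign_strahler_orders",
    "point_inside_lobe",
    "points_inside_lobe",
    "LOBE_LABELS",
]


class TreeStructureError(ValueError):
    """Raised when a centreline graph is not a valid bifurcating tree."""


class GeometryError(ValueError):
    """Raised for invalid surfaces or degenerate geometric queries."""


@dataclass
class Node:
    id: int
    position: np.ndarray  # (3,) mm
    radius: float  # lumen radius, mm

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"node {self.id}: position must be a finite 3-vector")
        if not (self.radius > 0):
            raise ValueError(f"node {self.id}: radius must be positive")


@dataclass
class Branch:
    """One airway from bifurcation (or inlet) to the next bifurcation (or tip)."""

    id: int
    node_path: List[int]  # ordered node ids, proximal -> distal, length >= 2
    parent: Optional[int] = None
    children: List[int] = field(default_factory=list)
    origin: str = "ct"  # "ct" | "generated"
    lobe: Optional[str] = None  # one of LOBE_LABELS or None
    generation: Optional[int] = None
    horsfield: Optional[int] = None
    strahler: Optional[int] = None
    diameter: Optional[float] = None  # assigned diameter (generated branches), mm


@dataclass
class AirwayTree:
    nodes: Dict[int, Node] = field(default_factory=dict)
    branches: Dict[int, Branch] = field(default_factory=dict)
    root_branch: Optional[int] = None

    # -- construction helpers ------------------------------------------------
    def add_node(self, position, radius, node_id: Optional[int] = None) -> int:
        if node_id is None:
            node_id = len(self.nodes)
            while node_id in self.nodes:
                node_id += 1
        self.nodes[node_id] = Node(node_id, np.asarray(position, float), float(radius))
        return node_id

    def add_branch(self, node_path: Sequence[int], parent: Optional[int] = None,
                   origin: str = "ct", lobe: Optional[str] = None,
                   branch_id: Optional[int] = None) -> int:
        if branch_id is None:
            branch_id = len(self.branches)
            while branch_id in self.branches:
                branch_id += 1
        path = [int(n) for n in node_path]
        if len(path) < 2:
            raise TreeStructureError(f"branch {branch_id}: path needs >= 2 nodes")
        br = Branch(branch_id, path, parent=parent, origin=origin, lobe=lobe)
        if parent is not None:
            pbr = self.branches[parent]
            if len(pbr.children) >= 2:
                raise TreeStructureError(
                    f"branch {parent} would get a third child (trifurcation)")
            if path[0] != pbr.node_path[-1]:
                raise TreeStructureError(
                    f"branch {branch_id} must start at parent {parent}'s distal node")
            pbr.children.append(branch_id)
        else:
            if self.root_branch is not None:
                raise TreeStructureError("tree already has a root branch")
            self.root_branch = branch_id
        self.branches[branch_id] = br
        return branch_id

    # -- geometry ------------------------------------------------------------
    def path_points(self, branch_id: int) -> np.ndarray:
        br = self.branches[branch_id]
        return np.array([self.nodes[n].position for n in br.node_path])

    def path_radii(self, branch_id: int) -> np.ndarray:
        br = self.branches[branch_id]
        return np.array([self.nodes[n].radius for n in br.node_path])

    def branch_length(self, branch_id: int) -> float:
        pts = self.path_points(branch_id)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def branch_diameter(self, branch_id: int) -> float:
        """Branch diameter D: the assigned diameter for generated branches,
        the path-mean of 2*radius for measured (ct) branches.

        The mean runs over the nodes the branch owns (every path node past
        the junction shared with its parent), so scaling a branch's own radii
        by f scales D by f exactly.
        """
        br = self.branches[branch_id]
        if br.diameter is not None:
            return br.diameter
        radii = self.path_radii(branch_id)
        if br.parent is not None:
            radii = radii[1:]
        return float(2.0 * radii.mean())

    def branch_direction(self, branch_id: int) -> np.ndarray:
        """Unit end-to-end chord, proximal -> distal."""
        pts = self.path_points(branch_id)
        v = pts[-1] - pts[0]
        n = np.linalg.norm(v)
        if n == 0:
            raise GeometryError(f"branch {branch_id}: zero end-to-end length")
        return v / n

    def distal_position(self, branch_id: int) -> np.ndarray:
        return self.nodes[self.branches[branch_id].node_path[-1]].position

    # -- traversal -----------------------------------------------------------
    def terminal_branches(self) -> List[int]:
        return [b.id for b in self.branches.values() if not b.children]

    def branches_preorder(self) -> List[int]:
        order, stack = [], [self.root_branch]
        while stack:
            b = stack.pop()
            order.append(b)
            stack.extend(reversed(self.branches[b].children))
        return order

    def branches_postorder(self) -> List[int]:
        return list(reversed(self.branches_preorder()))

    def validate(self) -> None:
        if self.root_branch is None or self.root_branch not in self.branches:
            raise TreeStructureError("missing root branch")
        seen = set()
        for b in self.branches_preorder():
            if b in seen:
                raise TreeStructureError("cycle detected among branches")
            seen.add(b)
            br = self.branches[b]
            if len(br.children) not in (0, 2):
                raise TreeStructureError(
                    f"branch {b} has {len(br.children)} children; tree must bifurcate")
            pts = self.path_points(b)
            if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0):
                raise TreeStructureError(f"branch {b} has consecutive duplicate nodes")
        if seen != set(self.branches):
            raise TreeStructureError("tree is not connected")

    def copy(self) -> "AirwayTree":
        t = AirwayTree()
        for nid, n in self.nodes.items():
            t.nodes[nid] = Node(nid, n.position.copy(), n.radius)
        for bid, b in self.branches.items():
            nb = Branch(bid, list(b.node_path), b.parent, list(b.children),
                        b.origin, b.lobe, b.generation, b.horsfield,
                        b.strahler, b.diameter)
            t.branches[bid] = nb
        t.root_branch = self.root_branch
        return t


# ---------------------------------------------------------------------------
# Centreline graph -> branch tree
# ---------------------------------------------------------------------------

def build_branches_from_centreline(nodes, edges, root_node: Optional[int] = None,
                                   origins=None, lobes=None) -> AirwayTree:
    """Collapse a node/edge centreline graph into a branch tree.

    Chains of degree-2 nodes become interior points of a single branch, so a
    branch spans from one bifurcation (or the inlet) to the next bifurcation
    (or a distal tip).

    Parameters
    ----------
    nodes : iterable of (id, position, radius) or Node
    edges : iterable of (parent_node_id, child_node_id)
    root_node : inlet node id; if omitted, inferred as the unique node that
        never appears as a child.
    origins, lobes : optional dicts mapping an edge (parent, child) to its
        origin tag / lobe label; a branch takes the tag of its first edge.
    """
    tree = AirwayTree()
    for item in nodes:
        if isinstance(item, Node):
            tree.nodes[item.id] = item
        else:
            nid, pos, rad = item
            tree.nodes[int(nid)] = Node(int(nid), np.asarray(pos, float), float(rad))

    children: Dict[int, List[int]] = {}
    has_parent = set()
    edge_list = [(int(a), int(b)) for a, b in edges]
    for a, b in edge_list:
        if a not in tree.nodes or b not in tree.nodes:
            raise TreeStructureError(f"edge ({a},{b}) references unknown node")
        children.setdefault(a, []).append(b)
        if b in has_parent:
            raise TreeStructureError(f"node {b} has two parents (cycle or merge)")
        has_parent.add(b)

    if root_node is None:
        roots = [n for n in tree.nodes if n not in has_parent and n in children]
        if len(roots) != 1:
            raise TreeStructureError(
                f"cannot infer a unique inlet node (candidates: {sorted(roots)})")
        root_node = roots[0]
    root_node = int(root_node)

    for n, ch in children.items():
        if len(ch) > 2:
            raise TreeStructureError(
                f"node {n} has {len(ch)} children: trifurcations are rejected")

    # walk degree-2 chains from the root
    visited_nodes = {root_node}
    n_edges_walked = 0
    stack: List[Tuple[int, Optional[int]]] = [(root_node, None)]  # (start node, parent branch)
    while stack:
        start, parent_branch = stack.pop()
        for first in sorted(children.get(start, [])):
            path = [start, first]
            n_edges_walked += 1
            cur = first
            while len(children.get(cur, [])) == 1:
                nxt = children[cur][0]
                path.append(nxt)
                n_edges_walked += 1
                if n_edges_walked > len(edge_list):
                    raise TreeStructureError("cycle detected in centreline graph")
                cur = nxt
            for n in path[1:]:
                if n in visited_nodes:
                    raise TreeStructureError("cycle detected in centreline graph")
                visited_nodes.add(n)
            key = (path[0], path[1])
            bid = tree.add_branch(
                path, parent=parent_branch,
                origin=(origins or {}).get(key, "ct"),
                lobe=(lobes or {}).get(key))
            if children.get(cur):
                stack.append((cur, bid))

    if n_edges_walked != len(edge_list):
        raise TreeStructureError(
            "centreline graph is disconnected or contains a cycle "
            f"({n_edges_walked} of {len(edge_list)} edges reachable from the inlet)")
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Orderings
# ---------------------------------------------------------------------------

def assign_generations(tree: AirwayTree) -> AirwayTree:
    """Weibel generation numbers: trachea (root) is generation 0, each child
    is its parent's generation + 1."""
    for b in tree.branches_preorder():
        br = tree.branches[b]
        br.generation = 0 if br.parent is None else tree.branches[br.parent].generation + 1
    return tree


def assign_horsfield_orders(tree: AirwayTree) -> AirwayTree:
    """Horsfield order: terminals are order 1; a parent is one more than its
    highest-ordered child.  The root carries the maximal order N."""
    for b in tree.branches_postorder():
        br = tree.branches[b]
        if not br.children:
            br.horsfield = 1
        else:
            br.horsfield = max(tree.branches[c].horsfield for c in br.children) + 1
    return tree


def assign_strahler_orders(tree: AirwayTree) -> AirwayTree:
    """Strahler order: terminals are 1; a parent increments only when both
    children share the same order, otherwise it takes the larger."""
    for b in tree.branches_postorder():
        br = tree.branches[b]
        if not br.children:
            br.strahler = 1
        else:
            s = [tree.branches[c].strahler for c in br.children]
            br.strahler = s[0] + 1 if s[0] == s[1] else max(s)
    return tree


# ---------------------------------------------------------------------------
# Lobe surfaces and point containment
# ---------------------------------------------------------------------------

@dataclass
class LobeSurface:
    """Closed triangulated surface bounding one lung lobe (mm units)."""

    vertices: np.ndarray  # (nv, 3)
    triangles: np.ndarray  # (nt, 3) int
    label: Optional[str] = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self._mesh = None

    @property
    def mesh(self) -> trimesh.Trimesh:
        if self._mesh is None:
            self._mesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.triangles, process=False)
        return self._mesh

    def validate(self) -> None:
        m = self.mesh
        if not m.is_watertight:
            edges = m.edges_sorted
            uniq, counts = np.unique(edges, axis=0, return_counts=True)
            bad = uniq[counts != 2][:10]
            raise GeometryError(
                f"surface {self.label!r} is not watertight; boundary/overused "
                f"edges (first 10): {bad.tolist()}")
        if not m.is_winding_consistent:
            raise GeometryError(f"surface {self.label!r} has inconsistent winding")
        if m.volume <= 0:
            raise GeometryError(f"surface {self.label!r} encloses non-positive volume")

    @property
    def volume(self) -> float:
        return float(abs(self.mesh.volume))

    @property
    def bounding_box_diagonal(self) -> float:
        """V_b: diagonal length of the axis-aligned bounding box, mm."""
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return float(np.linalg.norm(hi - lo))

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])


# fixed table of retry directions: classification is deterministic and
# independent of call order
_RAY_DIRS = np.random.default_rng(0x5EED).normal(size=(16, 3))
_RAY_DIRS /= np.linalg.norm(_RAY_DIRS, axis=1, keepdims=True)
_RAY_DIRS[0] = np.array([0.29871096, 0.58114311, 0.75698819])


def _moller_trumbore(origins: np.ndarray, direction: np.ndarray,
                     tri: np.ndarray, scale: float):
    """Return (crossings, degenerate) per origin for one shared ray direction."""
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    pvec = np.cross(direction, e2)  # (m, 3)
    det = (e1 * pvec).sum(axis=1)  # (m,)
    eps_det = 1e-12 * scale * scale
    ok = np.abs(det) > eps_det
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

    tvec = origins[:, None, :] - v0[None, :, :]  # (n, m, 3)
    u = (tvec * pvec[None]).sum(axis=2) * inv_det[None]
    qvec = np.cross(tvec, e1[None, :, :])
    v = (qvec * direction).sum(axis=2) * inv_det[None]
    t = (qvec * e2[None, :, :]).sum(axis=2) * inv_det[None]

    eps_t = 1e-9 * scale
    bary_tol = 1e-9
    hit = ok[None] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > eps_t)
    near = ok[None] & (t > eps_t) & (
        (np.abs(u) < bary_tol) | (np.abs(v) < bary_tol)
        | (np.abs(1.0 - u - v) < bary_tol))
    grazing = ok[None] & (np.abs(t) <= eps_t) & (u >= -bary_tol) & (v >= -bary_tol) \
        & (u + v <= 1 + bary_tol)
    crossings = hit.sum(axis=1)
    degenerate = (near | grazing).any(axis=1)
    return crossings, degenerate


def points_inside_lobe(points: np.ndarray, surface: LobeSurface,
                       validate: bool = True, max_retries: int = 12) -> np.ndarray:
    """Ray-casting point containment for a batch of query points.

    A point is inside iff a ray from it crosses the closed surface an odd
    number of times.  Queries whose ray grazes a vertex/edge (degenerate hit)
    are retried with a fresh random direction from a fixed stream, so results
    are robust and reproducible.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if validate:
        surface.validate()
    tri = surface.vertices[surface.triangles]  # (m, 3, 3)
    scale = max(surface.bounding_box_diagonal, 1e-30)

    inside = np.zeros(len(points), dtype=bool)
    pending = np.arange(len(points))
    # chunk so the (n, m) broadcast stays below ~48 MB
    chunk = max(1, int(2.0e6 / max(len(tri), 1)))
    for attempt in range(min(max_retries, len(_RAY_DIRS))):
        direction = _RAY_DIRS[attempt]
        still = []
        for s in range(0, len(pending), chunk):
            idx = pending[s:s + chunk]
            crossings, degen = _moller_trumbore(points[idx], direction, tri, scale)
            inside[idx] = (crossings % 2) == 1
            still.append(idx[degen])
        pending = np.concatenate(still) if still else np.array([], dtype=int)
        if len(pending) == 0:
            break
    return inside


def point_inside_lobe(p, surface: LobeSurface, validate: bool = True) -> bool:
    """Single-point convenience wrapper around :func:`points_inside_lobe`."""
    return bool(points_inside_lobe(np.asarray(p, float)[None, :], surface,
                                   validate=validate)[0])
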