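"""Synthetic lobar surfaces and central airway trees.

This module stands in for the imaging front end of the pipeline: it produces
five watertight lobe-like host volumes summing to an adult inspiratory lung
volume, and a central airway tree (trachea to roughly generation 6) whose
distal tips lie inside the lobes and whose radii follow a Weibel-like
homothety.  An optional heterogeneous lumen constriction emulates the
asthmatic phenotype (a random subset of airways narrowed by random factors).

The anatomy is deliberately idealised: lobes are ellipsoids flattened against
oblique fissure planes, positioned in anatomically plausible left/right,
upper/lower slots.  Volume control and watertightness are exact; shape realism
is not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import trimesh

from .core import (
    AirwayTree,
    GeometryError,
    LobeSurface,
    LOBE_LABELS,
    assign_generations,
    point_inside_lobe,
    points_inside_lobe,
)

__all__ = [
    "AnatomyConfig",
    "ConstrictionSpec",
    "make_lobe_surfaces",
    "make_central_tree",
    "make_anatomy",
    "apply_constriction",
]

DEFAULT_LOBE_FRACTIONS = {"RUL": 0.20, "RML": 0.10, "RLL": 0.25,
                          "LUL": 0.20, "LLL": 0.25}


@dataclass
class ConstrictionSpec:
    """Heterogeneous lumen narrowing: a random fraction of measured branches
    has all its radii multiplied by a factor drawn uniformly from
    ``factor_range``."""

    fraction_of_branches: float = 0.3
    factor_range: Tuple[float, float] = (0.4, 0.8)

    def __post_init__(self):
        lo, hi = self.factor_range
        if not (0 < lo <= hi):
            raise ValueError("constriction factors must be positive")
        if not (0 <= self.fraction_of_branches <= 1):
            raise ValueError("fraction_of_branches must be in [0, 1]")


@dataclass
class AnatomyConfig:
    total_lung_volume: float = 5500.0  # mL, adult inspiratory volume
    lobe_fractions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOBE_FRACTIONS))
    central_generations: int = 10  # hard cap on segmented-tree depth
    # airways narrower than this are invisible on CT and end the segmented
    # tree; with the calibre ratios below the terminal segmented generations
    # then span ~4-9 with mean ~6, as in imaging-derived trees.  0 disables.
    min_segmentable_diameter: float = 2.0  # mm
    trachea_diameter: float = 18.0  # mm
    trachea_length: float = 100.0  # mm
    # central-airway calibre inheritance, emulating CT morphometry: the child
    # feeding the larger subtree narrows by major_diameter_ratio, its sibling
    # by minor_diameter_ratio (means match D/D_parent ~ 0.70 of measured
    # central airways).  Setting child_diameter_ratio forces a symmetric
    # homothety instead.
    major_diameter_ratio: float = 0.78
    minor_diameter_ratio: float = 0.63
    child_diameter_ratio: Optional[float] = None
    length_to_diameter: float = 3.7  # descriptive target, recorded in manifests
    constriction: Optional[ConstrictionSpec] = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.total_lung_volume <= 0 or self.trachea_diameter <= 0 \
                or self.trachea_length <= 0:
            raise ValueError("anatomy dimensions must be positive")
        if set(self.lobe_fractions) != set(LOBE_LABELS):
            raise ValueError(f"lobe_fractions must have keys {LOBE_LABELS}")
        s = sum(self.lobe_fractions.values())
        if abs(s - 1.0) > 1e-9 or min(self.lobe_fractions.values()) <= 0:
            raise ValueError("lobe fractions must be positive and sum to 1")
        for r in (self.major_diameter_ratio, self.minor_diameter_ratio,
                  self.child_diameter_ratio):
            if r is not None and not (0 < r < 1):
                raise ValueError("diameter ratios must be in (0, 1)")

    def child_ratios(self) -> Tuple[float, float]:
        """(major, minor) per-bifurcation diameter ratios."""
        if self.child_diameter_ratio is not None:
            return self.child_diameter_ratio, self.child_diameter_ratio
        return self.major_diameter_ratio, self.minor_diameter_ratio


# ---------------------------------------------------------------------------
# Lobe surfaces
# ---------------------------------------------------------------------------

# Base geometry per lobe: ellipsoid centre, semi-axes (mm, for a 5.5 L lung)
# and an oblique fissure plane (point, outward normal); vertices beyond the
# plane are flattened onto it.  z slabs are disjoint within each lung and the
# two lungs are separated in x, so lobes cannot overlap.
_LOBE_GEOMETRY = {
    # label:   centre            semi-axes      fissure point      fissure normal
    "RUL": ((-78.0, 0.0, 95.0), (68.0, 85.0, 52.0), (-78.0, 20.0, 60.0), (0.0, 0.35, -0.94)),
    "RML": ((-78.0, 25.0, 5.0), (64.0, 78.0, 30.0), (-78.0, 25.0, 22.0), (0.0, -0.20, 0.98)),
    "RLL": ((-78.0, -5.0, -95.0), (68.0, 88.0, 62.0), (-78.0, -20.0, -55.0), (0.0, 0.45, 0.89)),
    "LUL": ((78.0, 0.0, 78.0), (62.0, 69.0, 70.0), (78.0, 20.0, 30.0), (0.0, 0.35, -0.94)),
    "LLL": ((78.0, -5.0, -78.0), (64.0, 81.0, 72.0), (78.0, -20.0, -35.0), (0.0, 0.45, 0.89)),
}


def _flatten_against_plane(vertices: np.ndarray, point, normal) -> np.ndarray:
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    d = (vertices - np.asarray(point, float)) @ n
    out = vertices.copy()
    mask = d > 0
    out[mask] -= d[mask, None] * n
    return out


def make_lobe_surfaces(config: AnatomyConfig,
                       subdivisions: int = 3) -> List[LobeSurface]:
    """Build the five watertight lobe surfaces.

    Each lobe is a subdivided icosphere stretched to an ellipsoid, flattened
    against an oblique fissure plane (projecting vertices keeps connectivity,
    hence watertightness), then rescaled in x/y about its centre so the
    enclosed volume matches ``total_lung_volume * fraction`` exactly.
    """
    total_mm3 = config.total_lung_volume * 1000.0  # mL -> mm^3
    # the overall lung scale tracks the cube root of total volume
    lin = (config.total_lung_volume / 5500.0) ** (1.0 / 3.0)
    surfaces = []
    for label in LOBE_LABELS:
        frac = config.lobe_fractions[label]
        target = total_mm3 * frac
        centre, semi, fpoint, fnormal = _LOBE_GEOMETRY[label]
        centre = np.asarray(centre) * lin
        semi = np.asarray(semi) * lin
        fpoint = np.asarray(fpoint) * lin
        base = trimesh.creation.icosphere(subdivisions=subdivisions)
        verts = base.vertices * semi + centre
        verts = _flatten_against_plane(verts, fpoint, fnormal)
        mesh = trimesh.Trimesh(vertices=verts, faces=base.faces, process=False)
        vol = abs(mesh.volume)
        if vol <= 0:
            raise GeometryError(f"lobe {label}: degenerate base geometry")
        s_xy = np.sqrt(target / vol)
        if not (0.2 < s_xy < 5.0):
            raise ValueError(
                f"lobe {label}: requested fraction {frac} is infeasible for the "
                f"template geometry (xy scale {s_xy:.2f})")
        verts = (verts - centre) * np.array([s_xy, s_xy, 1.0]) + centre
        surf = LobeSurface(verts, base.faces.copy(), label=label)
        surf.validate()
        surfaces.append(surf)

    # pairwise disjoint bounding boxes guarantee non-overlap
    for i in range(len(surfaces)):
        for j in range(i + 1, len(surfaces)):
            lo_i, hi_i = surfaces[i].bounds
            lo_j, hi_j = surfaces[j].bounds
            if np.all(hi_i > lo_j) and np.all(hi_j > lo_i):
                raise ValueError(
                    f"lobes {surfaces[i].label} and {surfaces[j].label} overlap; "
                    "requested fractions are infeasible")
    return surfaces


# ---------------------------------------------------------------------------
# Central airway tree
# ---------------------------------------------------------------------------

def _lobe_cloud(lobe: LobeSurface, n_target: int, rng: np.random.Generator
                ) -> np.ndarray:
    """Quasi-uniform points strictly inside a lobe: a jittered lattice sized
    so roughly ``n_target`` points survive the containment filter."""
    spacing = (lobe.volume / max(n_target, 1)) ** (1.0 / 3.0)
    lo, hi = lobe.bounds
    axes = [np.arange(lo[k] + spacing / 2, hi[k], spacing) for k in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts + rng.uniform(-0.15, 0.15, size=pts.shape) * spacing
    inside = points_inside_lobe(pts, lobe, validate=False)
    pts = pts[inside]
    if len(pts) == 0:
        raise GeometryError(f"lobe {lobe.label}: no interior cloud points")
    return pts


def _split_cloud(points: np.ndarray, p_prox: np.ndarray, p_dist: np.ndarray):
    """Split a point cloud by the plane through its centroid and the parent
    branch axis (same rule as the distal growth algorithm)."""
    c = points.mean(axis=0)
    normal = np.cross(p_dist - p_prox, c - p_prox)
    nn = np.linalg.norm(normal)
    scale = np.linalg.norm(p_dist - p_prox) + np.linalg.norm(c - p_prox)
    if nn < 1e-9 * max(scale, 1.0) ** 2:
        normal = p_dist - p_prox  # fallback: plane normal to the parent axis
        nn = np.linalg.norm(normal)
    normal = normal / nn
    side = (points - c) @ normal
    a = np.flatnonzero(side >= 0)
    b = np.flatnonzero(side < 0)
    if len(a) == 0 or len(b) == 0:
        order = np.argsort(side, kind="stable")
        half = len(points) // 2
        a, b = order[:half], order[half:]
    return a, b


def make_central_tree(lobes: Sequence[LobeSurface], config: AnatomyConfig
                      ) -> AirwayTree:
    """Grow an idealised central tree (all branches tagged ``ct``).

    The trachea descends to a carina above the lungs; the tree then bisects a
    per-lobe point cloud recursively (the same plane-splitting rule used by
    the distal growth algorithm) down to ``central_generations``, with the
    final generation extending fully to its cloud centroid so tips land
    strictly inside the lobes.  Per-point radii follow
    ``trachea_radius * child_diameter_ratio ** generation``.
    """
    g = config.central_generations
    if g < 1:
        raise ValueError("central_generations must be >= 1")
    rng = np.random.default_rng(config.rng_seed)
    lin = (config.total_lung_volume / 5500.0) ** (1.0 / 3.0)

    last_err = None
    for attempt in range(5):
        clouds = [_lobe_cloud(lobe, 120, rng) for lobe in lobes]
        tree = _grow_central(clouds, lobes, config, lin)
        # verify every lobe holds at least one distal tip (only meaningful when
        # the tree has enough tips to cover the lobes)
        if 2 ** g < 2 * len(lobes):
            return tree
        tips = np.array([tree.distal_position(b) for b in tree.terminal_branches()])
        ok = True
        for lobe in lobes:
            if not points_inside_lobe(tips, lobe, validate=False).any():
                ok = False
                last_err = f"no distal tip inside lobe {lobe.label}"
                break
        if ok:
            return tree
    raise GeometryError(f"central tree generation failed after retries: {last_err}")


def _straight_path(tree: AirwayTree, start_node: int, end: np.ndarray,
                   radius: float, n_points: int = 5) -> List[int]:
    """Subdivide a straight branch so every branch has >= 4 path points."""
    p0 = tree.nodes[start_node].position
    path = [start_node]
    for i in range(1, n_points):
        f = i / (n_points - 1)
        path.append(tree.add_node(p0 + f * (end - p0), radius))
    return path


def _grow_central(clouds, lobes, config: AnatomyConfig, lin: float) -> AirwayTree:
    g = config.central_generations
    r0 = config.trachea_diameter / 2.0
    r_major, r_minor = config.child_ratios()
    all_pts = np.concatenate(clouds, axis=0)
    lobe_of_pt = np.concatenate([np.full(len(c), i) for i, c in enumerate(clouds)])

    tree = AirwayTree()
    carina = np.array([0.0, 0.0, 50.0 * lin])
    top = carina + np.array([0.0, 0.0, config.trachea_length])
    n_top = tree.add_node(top, r0)
    trachea_path = _straight_path(tree, n_top, carina, r0)
    trachea = tree.add_branch(trachea_path, origin="ct")

    def make_tip(bid: int, subset: np.ndarray) -> None:
        """Close a branch as a segmented-tree tip: its distal end must sit
        strictly inside a lobe (a tip outside lobar tissue would act as a
        wide-open outlet in the ventilation model)."""
        br = tree.branches[bid]
        dist = tree.nodes[br.node_path[-1]].position
        labels = lobe_of_pt[subset]
        host_i = np.bincount(labels).argmax()
        host = lobes[host_i]
        br.lobe = host.label
        if point_inside_lobe(dist, host, validate=False):
            return
        c_host = all_pts[subset[labels == host_i]].mean(axis=0)
        end = c_host
        for t in (0.25, 0.5, 0.75):
            cand = dist + t * (c_host - dist)
            if point_inside_lobe(cand, host, validate=False):
                end = cand
                break
        # re-aim the tip branch: straight resubdivision to the new end point
        p0 = tree.nodes[br.node_path[0]].position
        for i, nid in enumerate(br.node_path[1:], start=1):
            f = i / (len(br.node_path) - 1)
            tree.nodes[nid].position = p0 + f * (end - p0)

    # (branch id, point-subset indices, radius), grown breadth-first until the
    # depth cap or the CT visibility limit (child calibre) is reached
    min_d = config.min_segmentable_diameter or 0.0
    frontier = [(trachea, np.arange(len(all_pts)), r0)]
    gen = 1
    while frontier and gen <= g:
        nxt = []
        for bid, subset, parent_radius in frontier:
            pts = all_pts[subset]
            prox = tree.nodes[tree.branches[bid].node_path[0]].position
            dist = tree.nodes[tree.branches[bid].node_path[-1]].position
            if len(subset) < 2 or 2.0 * parent_radius * r_minor < min_d:
                make_tip(bid, subset)
                continue
            ia, ib = _split_cloud(pts, prox, dist)
            if len(ib) > len(ia):
                ia, ib = ib, ia  # the larger subtree takes the major calibre
            grown = []
            for side, ratio in ((ia, r_major), (ib, r_minor)):
                sub = subset[side]
                radius = parent_radius * ratio
                target_len = config.length_to_diameter * 2.0 * radius
                c = all_pts[sub].mean(axis=0)
                gap = np.linalg.norm(c - dist)
                if gap < 1e-9:
                    grown = None
                    break
                # branch length: the volume-filling 40% step, floored at the
                # measured L/D ratio, never overshooting the cloud centroid
                end = dist + min(gap, max(target_len, 0.4 * gap)) / gap * (c - dist)
                labels = lobe_of_pt[sub]
                host_i = np.bincount(labels).argmax()
                lobe = lobes[host_i].label if (labels == host_i).all() else None
                grown.append((end, radius, sub, lobe))
            if grown is None:
                make_tip(bid, subset)
                continue
            for end, radius, sub, lobe in grown:
                path = _straight_path(tree, tree.branches[bid].node_path[-1],
                                      end, radius)
                cid = tree.add_branch(path, parent=bid, origin="ct", lobe=lobe)
                nxt.append((cid, sub, radius))
        frontier = nxt
        gen += 1
    for bid, subset, _ in frontier:  # depth cap reached
        make_tip(bid, subset)
    assign_generations(tree)
    tree.validate()
    return tree


def make_anatomy(config: Optional[AnatomyConfig] = None
                 ) -> Tuple[List[LobeSurface], AirwayTree]:
    """Convenience front end: lobes + central tree (+ constriction if asked)."""
    config = config or AnatomyConfig()
    lobes = make_lobe_surfaces(config)
    tree = make_central_tree(lobes, config)
    if config.constriction is not None:
        tree = apply_constriction(tree, config.constriction, config.rng_seed)
    return lobes, tree


# ---------------------------------------------------------------------------
# Constriction
# ---------------------------------------------------------------------------

def apply_constriction(tree: AirwayTree, spec: ConstrictionSpec,
                       rng_seed: int) -> AirwayTree:
    """Narrow a random subset of measured (ct) branches in place on a copy.

    Each selected branch has the radii of the nodes it owns (all path nodes
    distal of the junction it shares with its parent; the root also owns its
    inlet node) multiplied by a factor drawn uniformly from
    ``spec.factor_range``.  With fraction 1 and a constant factor f this
    scales every nodal radius exactly once, so every branch diameter scales
    by f and every Poiseuille resistance by f**-4.
    """
    out = tree.copy()
    rng = np.random.default_rng(rng_seed)
    ct = sorted(b.id for b in out.branches.values() if b.origin == "ct")
    n_sel = int(round(spec.fraction_of_branches * len(ct)))
    sel = rng.choice(len(ct), size=n_sel, replace=False) if n_sel else []
    for k in sorted(sel):
        bid = ct[k]
        factor = rng.uniform(*spec.factor_range)
        br = out.branches[bid]
        owned = br.node_path[1:] if br.parent is not None else br.node_path
        for nid in owned:
            out.nodes[nid].radius *= factor
    return out
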