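"""Volume-filling generation of distal airway centrelines.

Extends a central (imaging-derived) airway tree into the lobar host volumes
down to acinar-scale terminal bronchioles.  A uniform grid of seed points is
laid inside each lobe, one seed per mean acinar volume (187 mm^3).  While
seeds remain, breadth-first over growth apices:

1. every remaining seed is assigned to the closest apex in its lobe; seeds
   farther than an adaptive threshold T from every apex are discarded,
2. the seeds of each apex are split into two sets by the plane through their
   centroid and the apex branch axis,
3. a new branch grows from the apex 40% of the way to each set's centroid
   (deviations beyond the maximum branching angle are rotated back to it, and
   endpoints leaving the lobe are pulled back by repeated halving),
4. a pathway whose set holds a single seed, or whose remaining reach (apex to
   set centroid) is below the prescribed 2 mm terminal length, ends in a
   terminal branch that consumes the closest remaining seed point.

The adaptive threshold T = max(V_b - D_l * n, 5 mm) (V_b the lobe bounding-box
diagonal, D_l = V_b / N with N the nominal maximum generation count, n the
growth round) suppresses spurious long branches late in growth, exploiting the
expected fall in branch length with generation.

The algorithm is deterministic: no randomness enters growth itself (an
optional seed-grid jitter is driven by ``rng_seed``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    AirwayTree,
    GeometryError,
    LobeSurface,
    assign_generations,
    points_inside_lobe,
)

__all__ = [
    "GenerationConfig",
    "SeedGrid",
    "GenerationError",
    "make_seed_grid",
    "adaptive_threshold",
    "assign_seeds_to_apices",
    "split_by_plane",
    "grow_point",
    "clamp_branching_angle",
    "check_terminal",
    "generate_complete_tree",
]


class GenerationError(RuntimeError):
    """Raised when distal growth cannot proceed or fails to terminate."""


@dataclass
class GenerationConfig:
    acinar_volume: float = 187.0  # mm^3, mean human acinar volume
    growth_fraction: float = 0.40  # fraction of apex->centroid distance grown
    min_branch_length: float = 2.0  # mm, below which a new branch is terminal
    threshold_floor: float = 5.0  # mm, floor of the adaptive threshold
    max_generations: int = 25  # N in the adaptive threshold (D_l = V_b / N)
    rng_seed: int = 0
    seed_jitter: float = 0.0  # optional lattice jitter as a fraction of spacing
    # maximum branching angle inherited from the base volume-filling
    # algorithm: a child deviating more than this from its parent direction is
    # rotated back to the limit.  None disables.
    angle_clamp: Optional[float] = 60.0  # degrees
    iteration_cap: int = 100  # non-termination guard on growth rounds

    def __post_init__(self):
        if not (0 < self.growth_fraction < 1) and self.growth_fraction != 1.0:
            raise ValueError("growth_fraction must be in (0, 1]")
        for name in ("acinar_volume", "min_branch_length", "threshold_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SeedGrid:
    points: np.ndarray  # (n, 3) mm, all strictly inside the lobe
    spacing: float  # mm; spacing**3 == acinar volume
    lobe_label: Optional[str] = None


@dataclass
class GrowthStats:
    """Per-lobe accounting of the growth loop (seed conservation is exact)."""

    initial_seeds: Dict[str, int] = field(default_factory=dict)
    consumed: Dict[str, int] = field(default_factory=dict)
    discarded: Dict[str, int] = field(default_factory=dict)
    rounds: Dict[str, int] = field(default_factory=dict)
    per_round: Dict[str, List[Tuple[int, int, int, int]]] = field(default_factory=dict)
    # per_round rows: (round, assigned, discarded, consumed)
    terminal_causes: Dict[str, Dict[str, int]] = field(default_factory=dict)


def make_seed_grid(lobe: LobeSurface, acinar_volume: float = 187.0,
                   jitter: float = 0.0,
                   rng: Optional[np.random.Generator] = None) -> SeedGrid:
    """Cubic seed lattice inside a lobe, one point per mean acinar volume.

    Spacing is ``acinar_volume**(1/3)`` and the lattice is anchored at the
    lobe bounding-box minimum corner; points outside the lobe are dropped.
    """
    spacing = float(acinar_volume) ** (1.0 / 3.0)
    lo, hi = lobe.bounds
    if np.any(hi - lo < spacing):
        raise GeometryError(
            f"lobe {lobe.label}: bounding box smaller than one seed spacing")
    axes = [np.arange(lo[k], hi[k] + 0.5 * spacing, spacing) for k in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape) * spacing
    inside = points_inside_lobe(pts, lobe, validate=False)
    pts = pts[inside]
    if len(pts) == 0:
        raise GeometryError(f"lobe {lobe.label}: no seed points inside")
    return SeedGrid(points=pts, spacing=spacing, lobe_label=lobe.label)


def adaptive_threshold(v_b: float, d_l: float, n: int,
                       floor: float = 5.0) -> float:
    """T = max(V_b - D_l * n, floor); V_b is the lobe bounding-box diagonal."""
    return max(v_b - d_l * n, floor)


def assign_seeds_to_apices(apex_positions: np.ndarray, seed_points: np.ndarray,
                           threshold: float) -> Tuple[np.ndarray, np.ndarray]:
    """Nearest-apex assignment with a hard distance cutoff.

    Returns ``(nearest, assigned)``: for each seed the index of its closest
    apex (ties go to the lowest index) and whether it lies within
    ``threshold`` (inclusive) of that apex; seeds beyond the threshold are to
    be discarded permanently.
    """
    apex_positions = np.atleast_2d(apex_positions)
    seed_points = np.atleast_2d(seed_points)
    if len(apex_positions) == 0:
        return (np.full(len(seed_points), -1), np.zeros(len(seed_points), bool))
    if len(apex_positions) * len(seed_points) <= 1_000_000:
        d = np.linalg.norm(seed_points[:, None, :] - apex_positions[None], axis=2)
        nearest = d.argmin(axis=1)  # argmin takes the first (lowest) on ties
        dist = d[np.arange(len(seed_points)), nearest]
    else:
        dist, nearest = cKDTree(apex_positions).query(seed_points)
    return nearest, dist <= threshold


def split_by_plane(points: np.ndarray, p_prox: np.ndarray, p_dist: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Split seed points into two non-empty sets by the plane through their
    centroid and the two nodes of the parent branch.

    If centroid and parent nodes are collinear the fallback plane passes
    through the parent distal node normal to the parent direction.  If the
    plane still fails to separate (all points on it), the points are split in
    half along the projection, keeping both sides non-empty.
    """
    points = np.atleast_2d(points)
    if len(points) < 2:
        raise ValueError("need at least two points to split")
    c = points.mean(axis=0)
    normal = np.cross(p_dist - p_prox, c - p_prox)
    nn = np.linalg.norm(normal)
    scale = max(np.linalg.norm(p_dist - p_prox) * np.linalg.norm(c - p_prox), 1e-30)
    if nn < 1e-9 * scale:
        normal = np.asarray(p_dist, float) - np.asarray(p_prox, float)
        nn = np.linalg.norm(normal)
        if nn == 0:
            raise GeometryError("parent branch has zero length")
    normal = normal / nn
    side = (points - c) @ normal
    a = np.flatnonzero(side >= 0)
    b = np.flatnonzero(side < 0)
    if len(a) == 0 or len(b) == 0:
        order = np.argsort(side, kind="stable")
        half = max(len(points) // 2, 1)
        a, b = np.sort(order[:half]), np.sort(order[half:])
    return a, b


def grow_point(apex_position: np.ndarray, centroid: np.ndarray,
               growth_fraction: float) -> np.ndarray:
    """Endpoint of a new branch: ``growth_fraction`` of the way from the apex
    distal node towards the seed-set centroid."""
    apex_position = np.asarray(apex_position, float)
    centroid = np.asarray(centroid, float)
    if np.linalg.norm(centroid - apex_position) == 0:
        raise GeometryError("seed-set centroid coincides with the growth apex")
    return apex_position + growth_fraction * (centroid - apex_position)


def clamp_branching_angle(parent_direction: np.ndarray, apex_position: np.ndarray,
                          end: np.ndarray, max_angle_deg: float) -> np.ndarray:
    """Rotate a proposed branch end back towards the parent direction so the
    branching angle does not exceed ``max_angle_deg`` (length preserved)."""
    u = np.asarray(parent_direction, float)
    u = u / np.linalg.norm(u)
    v = np.asarray(end, float) - apex_position
    nv = np.linalg.norm(v)
    if nv == 0:
        return end
    cos_a = np.clip(v @ u / nv, -1.0, 1.0)
    limit = np.radians(max_angle_deg)
    if np.arccos(cos_a) <= limit:
        return end
    w = v - (v @ u) * u  # component normal to the parent direction
    nw = np.linalg.norm(w)
    if nw < 1e-12 * nv:  # anti-parallel: rotation plane undefined
        return end
    v_new = nv * (np.cos(limit) * u + np.sin(limit) * w / nw)
    return apex_position + v_new


def check_terminal(branch_length: float, subset_size: int,
                   min_branch_length: float = 2.0) -> bool:
    """A freshly grown branch is terminal if shorter than the prescribed
    length or if its seed set holds a single point."""
    return branch_length < min_branch_length or subset_size <= 1


def _consume_nearest(point: np.ndarray, seeds: np.ndarray,
                     alive: np.ndarray) -> Optional[int]:
    """Remove (and return) the alive seed closest to ``point``."""
    idx = np.flatnonzero(alive)
    if len(idx) == 0:
        return None
    d = np.linalg.norm(seeds[idx] - point, axis=1)
    j = idx[d.argmin()]
    alive[j] = False
    return int(j)


def generate_complete_tree(central: AirwayTree, lobes: Sequence[LobeSurface],
                           config: Optional[GenerationConfig] = None
                           ) -> Tuple[AirwayTree, GrowthStats]:
    """Grow the complete conducting tree from a central tree into the lobes.

    Returns a new tree (the input is not mutated) whose generated branches are
    tagged ``origin='generated'`` with their host lobe label, plus per-lobe
    growth statistics.  Seed conservation is exact: every seed is either
    consumed by a terminal branch or discarded by the threshold rule.
    """
    config = config or GenerationConfig()
    tree = central.copy()
    assign_generations(tree)
    stats = GrowthStats()
    rng = np.random.default_rng(config.rng_seed)

    tips = tree.terminal_branches()
    tip_pos = np.array([tree.distal_position(b) for b in tips])
    claimed = set()
    for lobe in lobes:
        inside = points_inside_lobe(tip_pos, lobe, validate=False)
        lobe_tips = [b for b, ok in zip(tips, inside) if ok and b not in claimed]
        if not lobe_tips:
            raise GenerationError(
                f"lobe {lobe.label} contains no central airway tip")
        claimed.update(lobe_tips)
        _grow_lobe(tree, lobe, lobe_tips, config, stats, rng)
    return tree, stats


def _grow_lobe(tree: AirwayTree, lobe: LobeSurface, start_apices: List[int],
               config: GenerationConfig, stats: GrowthStats,
               rng: np.random.Generator) -> None:
    label = lobe.label or "?"
    grid = make_seed_grid(lobe, config.acinar_volume,
                          jitter=config.seed_jitter, rng=rng)
    seeds = grid.points
    alive = np.ones(len(seeds), dtype=bool)
    v_b = lobe.bounding_box_diagonal
    d_l = v_b / config.max_generations

    stats.initial_seeds[label] = len(seeds)
    consumed = discarded = 0
    causes = {"single_point": 0, "short": 0, "apex_single": 0,
              "containment": 0, "degenerate": 0}
    log: List[Tuple[int, int, int, int]] = []
    for br in start_apices:
        tree.branches[br].lobe = tree.branches[br].lobe or label

    apices = sorted(start_apices)
    n = 0
    while alive.any() and apices:
        if n > config.iteration_cap:
            raise GenerationError(
                f"lobe {label}: growth did not terminate in "
                f"{config.iteration_cap} rounds ({alive.sum()} seeds left, "
                f"{len(apices)} apices)")
        t = adaptive_threshold(v_b, d_l, n, config.threshold_floor)
        apex_pos = np.array([tree.distal_position(b) for b in apices])
        live_idx = np.flatnonzero(alive)
        nearest, ok = assign_seeds_to_apices(apex_pos, seeds[live_idx], t)
        n_assigned = int(ok.sum())
        too_far = live_idx[~ok]
        alive[too_far] = False
        discarded += len(too_far)
        round_consumed = 0

        # group assigned seeds by apex
        groups: Dict[int, np.ndarray] = {}
        for ai in range(len(apices)):
            sel = live_idx[ok & (nearest == ai)]
            if len(sel):
                groups[ai] = sel

        # propose children for every apex, then batch the containment checks
        proposals = []  # (apex list-pos, subset, endpoint, forced_terminal)
        closed = set()  # apices that grow children or terminate this round
        for ai in range(len(apices)):
            sub = groups.get(ai)
            if sub is None:
                continue  # no seeds this round: the apex stays open
            bid = apices[ai]
            apos = tree.distal_position(bid)
            if len(sub) == 1:
                # cannot bisect one point: the apex itself closes as terminal
                # and consumes its seed (the closest remaining by construction)
                if _consume_nearest(apos, seeds, alive) is not None:
                    consumed += 1
                    round_consumed += 1
                causes["apex_single"] += 1
                closed.add(bid)
                continue
            ppos = tree.nodes[tree.branches[bid].node_path[0]].position
            ia, ib = split_by_plane(seeds[sub], ppos, apos)
            pair = []
            for side in (ia, ib):
                s = sub[side]
                centroid = seeds[s].mean(axis=0)
                try:
                    end = grow_point(apos, centroid, config.growth_fraction)
                except GeometryError:
                    pair = None  # a degenerate side: the whole apex closes
                    break
                if config.angle_clamp is not None:
                    end = clamp_branching_angle(apos - ppos, apos, end,
                                                config.angle_clamp)
                pair.append([ai, s, end, False,
                             float(np.linalg.norm(centroid - apos))])
            if pair is None:
                if _consume_nearest(apos, seeds, alive) is not None:
                    consumed += 1
                    round_consumed += 1
                causes["degenerate"] += 1
                closed.add(bid)
            else:
                proposals.extend(pair)
                closed.add(bid)

        if proposals:
            ends = np.array([p[2] for p in proposals])
            apos_arr = np.array([tree.distal_position(apices[p[0]])
                                 for p in proposals])
            outside = ~points_inside_lobe(ends, lobe, validate=False)
            n_halved = np.zeros(len(ends), dtype=int)
            halvings = 0
            while outside.any() and halvings < 10:
                ends[outside] = apos_arr[outside] + 0.5 * (
                    ends[outside] - apos_arr[outside])
                n_halved[outside] += 1
                outside[outside] = ~points_inside_lobe(
                    ends[outside], lobe, validate=False)
                halvings += 1
            # more than 5 halvings (or never back inside): branch closes
            for k, p in enumerate(proposals):
                p[2] = ends[k]
                if n_halved[k] > 5 or outside[k]:
                    p[3] = True

        new_apices: List[int] = []
        for ai, sub, end, forced, reach in proposals:
            bid = apices[ai]
            apos = tree.distal_position(bid)
            length = float(np.linalg.norm(end - apos))
            if length < 1e-9:
                # halving collapsed the branch onto the apex: give it a token
                # extent so the bifurcation stays intact, and close it
                direction = seeds[sub].mean(axis=0) - apos
                end = apos + 1e-6 * direction / np.linalg.norm(direction)
                length = 1e-6
                forced = True
            node = tree.add_node(end, tree.nodes[tree.branches[bid].node_path[-1]].radius)
            child = tree.add_branch([tree.branches[bid].node_path[-1], node],
                                    parent=bid, origin="generated", lobe=label)
            tree.branches[child].generation = tree.branches[bid].generation + 1
            if forced or check_terminal(reach, len(sub), config.min_branch_length):
                if forced:
                    causes["containment"] += 1
                elif len(sub) <= 1:
                    causes["single_point"] += 1
                else:
                    causes["short"] += 1
                if _consume_nearest(end, seeds, alive) is not None:
                    consumed += 1
                    round_consumed += 1
            else:
                new_apices.append(child)

        log.append((n, n_assigned, len(too_far), round_consumed))
        # open apices persist across rounds until they grow or terminate
        apices = sorted([b for b in apices if b not in closed] + new_apices)
        n += 1

    # apices exhausted with seeds left: no apex within any distance -> discard
    rest = int(alive.sum())
    if rest:
        alive[:] = False
        discarded += rest
        log.append((n, 0, rest, 0))

    stats.terminal_causes[label] = causes
    stats.consumed[label] = consumed
    stats.discarded[label] = discarded
    stats.rounds[label] = n
    stats.per_round[label] = log
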