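"""Diameter assignment for generated airways from Horsfield order.

Generated centrelines are one-dimensional and need lumen diameters before
simulation.  Diameters follow a log-linear relationship in Horsfield order x:

    log D(x) = (x - N) log(Rd_H) + log(D_N)

i.e. ``D = D_N * Rd_H**(x - N)``, extrapolating down from a base airway of
order N and diameter D_N, with Rd_H = 1.15 (the anti-log of the slope of
diameter against Horsfield order).  Two base-airway choices are supported:

* ``tracheal`` — the trachea is the base for every generated branch;
* ``parent`` — each generated subtree uses its most distal measured (ct)
  ancestor as the base, which propagates any luminal narrowing measured in
  the central airways into the generated subtree.

Horsfield orders are computed on the *complete* tree (a measured branch's
order depends on the generated subtree hanging from it), which makes the
relationship well defined under both schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import AirwayTree, TreeStructureError, assign_horsfield_orders

__all__ = ["DiameterScheme", "diameter_from_order", "apply_scheme"]


@dataclass
class DiameterScheme:
    mode: str = "parent"  # "tracheal" | "parent"
    rd_h: float = 1.15
    diameter_floor: float = 0.2  # mm; guards deep asymmetric subtrees

    def __post_init__(self):
        if self.mode not in ("tracheal", "parent"):
            raise ValueError("mode must be 'tracheal' or 'parent'")
        if not self.rd_h > 1:
            raise ValueError("Rd_H must exceed 1")
        if self.diameter_floor < 0:
            raise ValueError("diameter_floor must be >= 0")


def diameter_from_order(x: int, n_base: int, d_base: float,
                        rd_h: float = 1.15, floor: float = 0.0) -> float:
    """D = D_N * Rd_H**(x - N), floored; x must not exceed the base order."""
    if x > n_base:
        raise ValueError(f"Horsfield order {x} exceeds base order {n_base}")
    if x < 1:
        raise ValueError("Horsfield orders start at 1")
    if d_base <= 0:
        raise ValueError("base diameter must be positive")
    return max(d_base * rd_h ** (x - n_base), floor)


def apply_scheme(tree: AirwayTree, scheme: DiameterScheme | None = None
                 ) -> AirwayTree:
    """Assign diameters to every generated branch in place; measured (ct)
    branches keep their per-point radii untouched.  Idempotent."""
    scheme = scheme or DiameterScheme()
    assign_horsfield_orders(tree)

    if scheme.mode == "tracheal":
        root = tree.branches[tree.root_branch]
        base_n = root.horsfield
        base_d = tree.branch_diameter(root.id)
        bases = {tree.root_branch: (base_n, base_d)}

        def base_for(br):
            return bases[tree.root_branch]
    else:
        bases = {}

        def base_for(br):
            anc = tree.branches[br.parent] if br.parent is not None else None
            while anc is not None and anc.origin != "ct":
                anc = tree.branches[anc.parent] if anc.parent is not None else None
            if anc is None:
                raise TreeStructureError(
                    f"generated branch {br.id} has no measured (ct) ancestor")
            if anc.id not in bases:
                bases[anc.id] = (anc.horsfield, tree.branch_diameter(anc.id))
            return bases[anc.id]

    for bid in tree.branches_preorder():
        br = tree.branches[bid]
        if br.origin != "generated":
            continue
        n_base, d_base = base_for(br)
        d = diameter_from_order(br.horsfield, n_base, d_base,
                                scheme.rd_h, scheme.diameter_floor)
        br.diameter = d
        # keep owned node radii in sync for I/O round trips
        for nid in br.node_path[1:]:
            tree.nodes[nid].radius = d / 2.0
    return tree
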