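import numpy as np
import pytest
import trimesh

from airwaygen import (
    AirwayTree,
    AnatomyConfig,
    DiameterScheme,
    GenerationConfig,
    LobeSurface,
    apply_scheme,
    assign_generations,
    assign_horsfield_orders,
    assign_strahler_orders,
    generate_complete_tree,
    make_anatomy,
)


def make_cube_surface(side=10.0, origin=(0.0, 0.0, 0.0), label="cube"):
    mesh = trimesh.creation.box(extents=(side, side, side))
    verts = mesh.vertices + np.asarray(origin) + side / 2.0
    return LobeSurface(verts, mesh.faces.copy(), label=label)


def make_ellipsoid_surface(semi=(10.0, 7.0, 5.0), subdivisions=3, label="ell"):
    base = trimesh.creation.icosphere(subdivisions=subdivisions)
    return LobeSurface(base.vertices * np.asarray(semi), base.faces.copy(),
                       label=label)


def random_binary_tree(rng, max_bifurcations=12, chain=0):
    """Random strictly bifurcating AirwayTree with optional degree-2 chains.

    Geometry is arbitrary but non-degenerate; radii taper with depth.
    """
    tree = AirwayTree()
    root_top = tree.add_node((0.0, 0.0, 0.0), 5.0)
    pos = np.array([0.0, 0.0, 10.0])
    n0 = tree.add_node(pos, 5.0)
    root = tree.add_branch([root_top, n0], origin="ct")
    leaves = [(root, pos, 1)]
    n_bif = int(rng.integers(1, max_bifurcations + 1))
    for _ in range(n_bif):
        k = int(rng.integers(0, len(leaves)))
        bid, p, depth = leaves.pop(k)
        for sgn in (-1.0, 1.0):
            d = rng.normal(size=3)
            d = d / np.linalg.norm(d) * (5.0 / depth + 1.0)
            d[0] += sgn * 3.0
            path = [tree.branches[bid].node_path[-1]]
            q = p
            for _ in range(chain):
                q = q + d / (chain + 1)
                path.append(tree.add_node(q, 5.0 / (depth + 1)))
            q = p + d
            path.append(tree.add_node(q, 5.0 / (depth + 1)))
            cid = tree.add_branch(path, parent=bid, origin="generated")
            leaves.append((cid, q, depth + 1))
    tree.validate()
    return tree


def oracle_horsfield(tree, bid):
    ch = tree.branches[bid].children
    if not ch:
        return 1
    return 1 + max(oracle_horsfield(tree, c) for c in ch)


def oracle_strahler(tree, bid):
    ch = tree.branches[bid].children
    if not ch:
        return 1
    a, b = (oracle_strahler(tree, c) for c in ch)
    return a + 1 if a == b else max(a, b)


@pytest.fixture(scope="session")
def tiny_anatomy():
    """Five miniature lobes + central tree (fast stand-in for the default)."""
    return make_anatomy(AnatomyConfig(total_lung_volume=150.0, rng_seed=3))


@pytest.fixture(scope="session")
def tiny_model(tiny_anatomy):
    """Complete tree grown on the miniature anatomy, parent-scheme diameters."""
    lobes, central = tiny_anatomy
    tree, stats = generate_complete_tree(central, lobes, GenerationConfig(rng_seed=3))
    assign_generations(tree)
    assign_horsfield_orders(tree)
    assign_strahler_orders(tree)
    apply_scheme(tree, DiameterScheme(mode="parent"))
    return {"lobes": lobes, "central": central, "tree": tree, "stats": stats}


def winding_number_inside(points, surface):
    """Generalized winding-number containment oracle (solid-angle sum)."""
    tri = surface.vertices[surface.triangles]
    out = np.empty(len(points), dtype=bool)
    chunk = max(1, int(2e6 / len(tri)))
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        a = tri[None, :, 0] - p[:, None]
        b = tri[None, :, 1] - p[:, None]
        c = tri[None, :, 2] - p[:, None]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("nij,nij->ni", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("nij,nij->ni", a, b) * lc
               + np.einsum("nij,nij->ni", b, c) * la
               + np.einsum("nij,nij->ni", c, a) * lb)
        omega = 2.0 * np.arctan2(num, den)
        out[s:s + chunk] = np.abs(omega.sum(axis=1)) > 2 * np.pi
    return out
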