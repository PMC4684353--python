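"""Bronchial-tree morphometry.

Per-branch geometry (branching angle, rotation angle, length, diameter,
minor/major child designation) and per-subject summary statistics, matching
the conventions of airway-tree cast studies:

* branching angle theta: angle between the parent's and the child's
  end-to-end direction vectors;
* rotation angle phi: angle between the plane of the parent and its sibling
  and the plane of the two children, folded into [0, 90] degrees;
* minor/major child: the smaller-/larger-diameter child of a bifurcation;
* L1/L2: shorter child length over longer child length at each bifurcation;
* theta is additionally stratified by parent diameter (>4, 4-3, 3-2, 2-1 mm,
  half-open downwards).

Branch directions use end-to-end chords: measured branches are polylines and
chords are stable against centreline noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import AirwayTree, GeometryError

__all__ = ["MorphometryReport", "branching_angle", "rotation_angle",
           "per_branch_table", "summarize"]

THETA_STRATA = ((4.0, np.inf), (3.0, 4.0), (2.0, 3.0), (1.0, 2.0))


def branching_angle(tree: AirwayTree, parent_id: int, child_id: int) -> float:
    """Angle (degrees, in [0, 180]) between parent and child chord vectors."""
    u = tree.branch_direction(parent_id)
    v = tree.branch_direction(child_id)
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def rotation_angle(tree: AirwayTree, branch_id: int) -> Optional[float]:
    """Angle (degrees, folded into [0, 90]) between the plane of ``branch_id``
    and its sibling and the plane of ``branch_id``'s two children.

    Returns None when either plane is degenerate (collinear directions) or the
    branch lacks a sibling or children.
    """
    br = tree.branches[branch_id]
    if br.parent is None or len(br.children) != 2:
        return None
    siblings = [c for c in tree.branches[br.parent].children if c != branch_id]
    if len(siblings) != 1:
        return None
    u_p = tree.branch_direction(branch_id)
    u_s = tree.branch_direction(siblings[0])
    u_c1 = tree.branch_direction(br.children[0])
    u_c2 = tree.branch_direction(br.children[1])
    n1 = np.cross(u_p, u_s)
    n2 = np.cross(u_c1, u_c2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        return None
    c = abs(n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def per_branch_table(tree: AirwayTree) -> pd.DataFrame:
    """One row per branch: orders, geometry, angles and minor/major flags."""
    rows = []
    for bid in tree.branches_preorder():
        br = tree.branches[bid]
        length = tree.branch_length(bid)
        if length <= 0:
            raise GeometryError(f"branch {bid} has zero length")
        rows.append({
            "branch": bid,
            "parent": br.parent if br.parent is not None else -1,
            "origin": br.origin,
            "lobe": br.lobe or "none",
            "generation": br.generation,
            "horsfield": br.horsfield,
            "strahler": br.strahler,
            "L": length,
            "D": tree.branch_diameter(bid),
            "theta": (branching_angle(tree, br.parent, bid)
                      if br.parent is not None else np.nan),
            "phi": rotation_angle(tree, bid) if len(br.children) == 2 else np.nan,
        })
    df = pd.DataFrame(rows).set_index("branch", drop=False)
    df.index.name = None

    d_parent = df["D"].reindex(df["parent"]).to_numpy()
    l_parent = df["L"].reindex(df["parent"]).to_numpy()
    df["D_parent"] = np.where(df["parent"] >= 0, d_parent, np.nan)
    df["L_parent"] = np.where(df["parent"] >= 0, l_parent, np.nan)

    # minor/major child per bifurcation (ties broken by branch id)
    df["is_minor"] = False
    df["is_major"] = False
    c1, c2, d1, d2 = _bifurcation_pairs(df)
    if len(c1):
        swap = (d2 < d1) | ((d2 == d1) & (c2 < c1))
        minor = np.where(swap, c2, c1)
        major = np.where(swap, c1, c2)
        df.loc[minor, "is_minor"] = True
        df.loc[major, "is_major"] = True
    return df


def _bifurcation_pairs(df: pd.DataFrame):
    """Child ids and diameters paired per bifurcation, lower id first."""
    child = df[df["parent"] >= 0].sort_values(["parent", "branch"])
    p = child["parent"].to_numpy()
    uniq, counts = np.unique(p, return_counts=True)
    two = set(uniq[counts == 2].tolist())
    keep = np.isin(p, list(two)) if len(two) else np.zeros(len(p), bool)
    sub = child[keep]
    ids = sub["branch"].to_numpy().reshape(-1, 2)
    ds = sub["D"].to_numpy().reshape(-1, 2)
    return ids[:, 0], ids[:, 1], ds[:, 0], ds[:, 1]


def _tree_means(df: pd.DataFrame) -> Dict[str, float]:
    """Per-subject (per-tree) means of the standard morphometric quantities."""
    child = df[df["parent"] >= 0]
    minor = child[child["is_minor"]]
    major = child[child["is_major"]]
    out: Dict[str, float] = {
        "theta": child["theta"].mean(),
        "phi": df["phi"].mean(),
        "theta_minor": minor["theta"].mean(),
        "theta_major": major["theta"].mean(),
        "L_over_D": (df["L"] / df["D"]).mean(),
        "L_over_D_minor": (minor["L"] / minor["D"]).mean(),
        "L_over_D_major": (major["L"] / major["D"]).mean(),
        "D_minor_over_D_major": np.nan,
        "D_over_D_parent": (child["D"] / child["D_parent"]).mean(),
        "D_minor_over_D_parent": (minor["D"] / minor["D_parent"]).mean(),
        "D_major_over_D_parent": (major["D"] / major["D_parent"]).mean(),
        "L_over_L_parent": (child["L"] / child["L_parent"]).mean(),
        "L1_over_L2": np.nan,
    }
    for lo, hi in THETA_STRATA:
        name = (f"theta_Dparent_gt{lo:g}mm" if np.isinf(hi)
                else f"theta_Dparent_{hi:g}to{lo:g}mm")
        sel = child[(child["D_parent"] > lo) & (child["D_parent"] <= hi)]
        out[name] = sel["theta"].mean() if len(sel) else np.nan

    # per-bifurcation ratios
    cc = child.sort_values(["parent", "branch"])
    p = cc["parent"].to_numpy()
    uniq, counts = np.unique(p, return_counts=True)
    two = uniq[counts == 2]
    if len(two):
        sub = cc[np.isin(p, two)]
        ds = np.sort(sub["D"].to_numpy().reshape(-1, 2), axis=1)
        ls = np.sort(sub["L"].to_numpy().reshape(-1, 2), axis=1)
        out["D_minor_over_D_major"] = float((ds[:, 0] / ds[:, 1]).mean())
        out["L1_over_L2"] = float((ls[:, 0] / ls[:, 1]).mean())
    return out


@dataclass
class MorphometryReport:
    per_branch: pd.DataFrame  # all trees concatenated, with a "tree" column
    subject_means: pd.DataFrame  # one row per tree
    summary: pd.DataFrame  # mean +/- SD across trees
    per_generation_radius: pd.DataFrame  # generation, mean, sd, count (mm)


def summarize(trees: Union[AirwayTree, Sequence[AirwayTree]]) -> MorphometryReport:
    """Morphometry of one tree or a cohort.

    Subject-level aggregation takes the mean of per-branch values within each
    tree, then mean and SD of those means across trees.
    """
    if isinstance(trees, AirwayTree):
        trees = [trees]
    tables, means = [], []
    for k, tree in enumerate(trees):
        df = per_branch_table(tree)
        df.insert(0, "tree", k)
        tables.append(df)
        means.append(_tree_means(df))
    per_branch = pd.concat(tables, ignore_index=True)
    subject_means = pd.DataFrame(means)
    summary = pd.DataFrame({
        "mean": subject_means.mean(),
        "sd": subject_means.std(ddof=1) if len(trees) > 1 else 0.0 * subject_means.mean(),
    })
    radii = per_branch.assign(radius=per_branch["D"] / 2.0)
    per_gen = (radii.groupby("generation")["radius"]
               .agg(mean="mean", sd="std", count="count").reset_index())
    return MorphometryReport(per_branch, subject_means, summary, per_gen)
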