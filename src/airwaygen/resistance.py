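"""Airflow resistance: Pedley-corrected Poiseuille tubes on a tree network.

Every airway is a circular tube.  Its viscous resistance is the Poiseuille
value

    R_p = 128 mu l / (pi d^4)

multiplied, at appreciable Reynolds number, by the Pedley entrance-flow
energy-dissipation factor

    Z = (c / 4) * sqrt(Re * d / l),      Re = 4 rho |Q| / (mu pi d),

applied only when Z > 1 (so R = Z R_p if Z > 1, else R_p; continuous at the
switch).  c = 1.85.  Longitudinal heterogeneity of measured airways is kept
by evaluating Poiseuille resistance per centreline segment (each segment uses
its local diameter, the mean of its endpoint diameters) and summing in
series; the entrance-effect factor Z develops once per airway, so it uses the
full branch length (this keeps the resistance of a uniform branch independent
of how finely its centreline is subdivided).

The network problem — conservation of mass at every bifurcation, R(Q) Q = dP
per branch, zero pressure at every distal tip and a prescribed inlet flow at
the trachea — is nonlinear because R depends on Q.  It is solved by fixed
point iteration: solve the linear nodal system at the current resistances
(direct sparse solve), update flows, update resistances, repeat until the
l-infinity relative residual falls below tolerance.  With the pure Poiseuille
model the first solve is exact.

Only the pressure drop from viscous dissipation is modelled; kinetic-energy
pressure changes are excluded, and |Q| in Re makes inspiration and expiration
symmetric (the expiratory increase of c is not modelled).

Internally everything is SI (m, Pa, m^3/s); tree geometry arrives in mm and
is converted here.  Totals can be reported in cmH2O.s/L for physiological
readability (1 cmH2O.s/L = 98066.5 Pa.s/m^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .core import AirwayTree

__all__ = [
    "FluidProperties",
    "FlowState",
    "ResistanceResult",
    "poiseuille_resistance",
    "pedley_resistance",
    "branch_resistance",
    "solve_flow",
    "total_resistance",
    "resistance_decomposition",
    "PA_S_PER_M3_TO_CMH2O_S_PER_L",
]

PA_S_PER_M3_TO_CMH2O_S_PER_L = 1.0 / 98066.5


@dataclass
class FluidProperties:
    """Air at body temperature."""

    density: float = 1.15  # kg/m^3
    viscosity: float = 1.92e-5  # Pa.s
    pedley_c: float = 1.85

    def __post_init__(self):
        if min(self.density, self.viscosity, self.pedley_c) <= 0:
            raise ValueError("fluid properties must be positive")


def poiseuille_resistance(length, diameter, viscosity: float = 1.92e-5):
    """R_p = 128 mu l / (pi d^4); SI units (m -> Pa.s/m^3)."""
    length = np.asarray(length, float)
    diameter = np.asarray(diameter, float)
    if np.any(length < 0) or np.any(diameter <= 0):
        raise ValueError("length must be >= 0 and diameter > 0")
    return 128.0 * viscosity * length / (np.pi * diameter ** 4)


def _pedley_factor(length, diameter, flow, props: FluidProperties):
    re = 4.0 * props.density * np.abs(flow) / (props.viscosity * np.pi * diameter)
    z = (props.pedley_c / 4.0) * np.sqrt(re * diameter / length)
    return np.maximum(z, 1.0)


def pedley_resistance(length, diameter, flow, props: Optional[FluidProperties] = None):
    """Pedley resistance of one tube: Z R_p when Z > 1, else R_p.

    Symmetric in the sign of the flow (only |Q| enters Re).
    """
    props = props or FluidProperties()
    rp = poiseuille_resistance(length, diameter, props.viscosity)
    return _pedley_factor(np.asarray(length, float), np.asarray(diameter, float),
                          flow, props) * rp


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

class _Network:
    """Per-segment arrays and junction topology for one tree (SI units)."""

    def __init__(self, tree: AirwayTree):
        self.tree = tree
        self.branch_ids = tree.branches_preorder()
        self.index = {b: i for i, b in enumerate(self.branch_ids)}
        seg_l, seg_d, seg_branch, seg_branch_l = [], [], [], []
        prox, dist = [], []
        junctions: Dict[int, int] = {}

        def jid(node):
            if node not in junctions:
                junctions[node] = len(junctions)
            return junctions[node]

        for i, bid in enumerate(self.branch_ids):
            br = tree.branches[bid]
            pts = tree.path_points(bid) * 1e-3
            ls = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if br.diameter is not None:
                ds = np.full(len(ls), br.diameter * 1e-3)
            else:
                r = tree.path_radii(bid) * 1e-3
                ds = r[:-1] + r[1:]  # mean of endpoint diameters
            seg_l.append(ls)
            seg_d.append(ds)
            seg_branch.append(np.full(len(ls), i))
            seg_branch_l.append(np.full(len(ls), ls.sum()))
            prox.append(jid(br.node_path[0]))
            dist.append(jid(br.node_path[-1]))

        self.seg_l = np.concatenate(seg_l)
        self.seg_d = np.concatenate(seg_d)
        self.seg_branch = np.concatenate(seg_branch)
        # the entrance-flow factor Z develops once per branch, so it is
        # evaluated with the full branch length even on subdivided polylines
        self.seg_branch_l = np.concatenate(seg_branch_l)
        self.prox = np.array(prox)
        self.dist = np.array(dist)
        self.junction_nodes = {v: k for k, v in junctions.items()}
        self.n_junctions = len(junctions)
        self.inlet = self.prox[self.index[tree.root_branch]]
        self.terminals = np.array(sorted(
            self.dist[self.index[b]] for b in tree.terminal_branches()))

    def branch_resistances(self, flows: np.ndarray, model: str,
                           props: FluidProperties) -> np.ndarray:
        rp = poiseuille_resistance(self.seg_l, self.seg_d, props.viscosity)
        if model == "pedley":
            q = flows[self.seg_branch]
            rp = rp * _pedley_factor(self.seg_branch_l, self.seg_d, q, props)
        out = np.zeros(len(self.branch_ids))
        np.add.at(out, self.seg_branch, rp)
        return out


def branch_resistance(tree: AirwayTree, branch_id: int, flow: float = 0.0,
                      model: str = "poiseuille",
                      props: Optional[FluidProperties] = None) -> float:
    """Series resistance of one branch (SI), per-segment local diameters."""
    props = props or FluidProperties()
    br = tree.branches[branch_id]
    pts = tree.path_points(branch_id) * 1e-3
    ls = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if br.diameter is not None:
        ds = np.full(len(ls), br.diameter * 1e-3)
    else:
        r = tree.path_radii(branch_id) * 1e-3
        ds = r[:-1] + r[1:]
    rp = poiseuille_resistance(ls, ds, props.viscosity)
    if model == "pedley":
        rp = rp * _pedley_factor(ls.sum(), ds, flow, props)
    return float(rp.sum())


@dataclass
class FlowState:
    branch_ids: List[int]
    flow: np.ndarray  # m^3/s per branch
    resistance: np.ndarray  # Pa.s/m^3 per branch (satisfies R*Q = dP)
    pressure: Dict[int, float]  # node id -> Pa at junction nodes
    inlet_flow: float
    inlet_pressure: float
    residual: float
    iterations: int
    model: str
    residual_history: List[float] = field(default_factory=list)

    def flow_of(self, branch_id: int) -> float:
        return float(self.flow[self.branch_ids.index(branch_id)])

    def resistance_of(self, branch_id: int) -> float:
        return float(self.resistance[self.branch_ids.index(branch_id)])


class SolverError(RuntimeError):
    pass


def solve_flow(tree: AirwayTree, inlet_flow: float, model: str = "pedley",
               props: Optional[FluidProperties] = None, tol: float = 1e-8,
               max_iter: int = 100,
               initial_flows: Optional[np.ndarray] = None) -> FlowState:
    """Solve the nonlinear ventilation network.

    Zero pressure at every distal tip, ``inlet_flow`` (m^3/s, >= 0) prescribed
    at the trachea entrance.  Fixed point iteration on the resistances with a
    direct sparse solve of the nodal system at each step; the initial guess is
    the Poiseuille solution unless ``initial_flows`` is given.  Converges in a
    single iteration for the Poiseuille model (and when re-entered with a
    converged state's flows).
    """
    if model not in ("poiseuille", "pedley"):
        raise ValueError("model must be 'poiseuille' or 'pedley'")
    if inlet_flow < 0:
        raise ValueError("inlet flow must be >= 0 (|Q| enters Re; the model "
                         "is symmetric in flow direction)")
    props = props or FluidProperties()
    net = _Network(tree)
    nb = len(net.branch_ids)

    free = np.ones(net.n_junctions, dtype=bool)
    free[net.terminals] = False
    fmap = -np.ones(net.n_junctions, dtype=int)
    fmap[free] = np.arange(free.sum())

    flows = np.zeros(nb) if initial_flows is None else np.asarray(initial_flows, float)
    history: List[float] = []
    resid = np.inf
    for it in range(1, max_iter + 1):
        r = net.branch_resistances(flows, model, props)
        g = 1.0 / r
        # nodal conductance system over free junctions
        rows, cols, vals, rhs = [], [], [], np.zeros(free.sum())
        pi, di = net.prox, net.dist
        for a, b in ((pi, di), (di, pi)):
            fa = fmap[a]
            on = fa >= 0
            rows.append(fa[on]); cols.append(fa[on]); vals.append(g[on])
            both = on & (fmap[b] >= 0)
            rows.append(fmap[a[both]]); cols.append(fmap[b[both]])
            vals.append(-g[both])
        rhs[fmap[net.inlet]] += inlet_flow
        mat = coo_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(free.sum(), free.sum())).tocsr()
        p_free = spsolve(mat, rhs)
        p = np.zeros(net.n_junctions)
        p[free] = p_free
        new_flows = (p[pi] - p[di]) * g

        # l-inf relative residual of R(Q) Q = dP at the new flows
        r_new = net.branch_resistances(new_flows, model, props)
        dp = p[pi] - p[di]
        scale = max(abs(p[net.inlet]), np.abs(dp).max(), 1e-300)
        resid = float(np.abs(r_new * new_flows - dp).max() / scale)
        history.append(resid)
        flows = new_flows
        if resid < tol or model == "poiseuille":
            pressure = {net.junction_nodes[j]: float(p[j])
                        for j in range(net.n_junctions)}
            return FlowState(net.branch_ids, flows, r, pressure,
                             inlet_flow, float(p[net.inlet]), resid, it,
                             model, history)
    raise SolverError(
        f"fixed point iteration did not converge in {max_iter} iterations; "
        f"residual trace: {history[-5:]}")


def total_resistance(state: FlowState) -> float:
    """Total tree resistance: inlet pressure over inlet flow (Pa.s/m^3)."""
    if state.inlet_flow == 0:
        raise ValueError("total resistance undefined at zero inlet flow; "
                         "solve with the poiseuille model at unit flow instead")
    return state.inlet_pressure / state.inlet_flow


def poiseuille_total_resistance(tree: AirwayTree,
                                props: Optional[FluidProperties] = None) -> float:
    """Vanishing-flow (Poiseuille) total resistance; independent of flow."""
    state = solve_flow(tree, 1.0, model="poiseuille", props=props)
    return total_resistance(state)


@dataclass
class ResistanceResult:
    total: float  # Pa.s/m^3
    total_cmH2O_s_per_L: float
    per_generation_fraction: Dict[int, float]
    generated_fraction: float
    per_branch_fraction: np.ndarray
    model: str
    inlet_flow: float
    iterations: int
    residual: float


def resistance_decomposition(tree: AirwayTree, state: FlowState) -> ResistanceResult:
    """Viscous power-dissipation decomposition of the total resistance.

    A branch's contribution is R_b Q_b^2 / (R_total Q_in^2): the share of
    total viscous power it dissipates.  The shares sum to 1 over the tree
    (power balance with zero terminal pressures), reduce to the pressure-drop
    share along any path on symmetric trees, and partition by generation and
    by measured-vs-generated origin.
    """
    p_in = state.inlet_pressure
    if p_in <= 0:
        raise ValueError("state has non-positive inlet pressure")
    frac = state.resistance * state.flow ** 2 / (p_in * state.inlet_flow)
    per_gen: Dict[int, float] = {}
    gen_frac = 0.0
    for f, bid in zip(frac, state.branch_ids):
        br = tree.branches[bid]
        per_gen[br.generation] = per_gen.get(br.generation, 0.0) + float(f)
        if br.origin == "generated":
            gen_frac += float(f)
    total = p_in / state.inlet_flow
    return ResistanceResult(
        total=total,
        total_cmH2O_s_per_L=total * PA_S_PER_M3_TO_CMH2O_S_PER_L,
        per_generation_fraction=dict(sorted(per_gen.items())),
        generated_fraction=gen_frac,
        per_branch_fraction=frac,
        model=state.model,
        inlet_flow=state.inlet_flow,
        iterations=state.iterations,
        residual=state.residual,
    )


def flow_conservation_error(tree: AirwayTree, state: FlowState) -> float:
    """Max junction imbalance |Q_parent - sum Q_children| / inlet flow."""
    idx = {b: i for i, b in enumerate(state.branch_ids)}
    worst = 0.0
    for bid in state.branch_ids:
        br = tree.branches[bid]
        if not br.children:
            continue
        imbalance = abs(state.flow[idx[bid]]
                        - sum(state.flow[idx[c]] for c in br.children))
        worst = max(worst, imbalance)
    q = state.inlet_flow if state.inlet_flow else 1.0
    return worst / q
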