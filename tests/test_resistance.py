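import numpy as np
import pytest
from scipy.optimize import brentq

from airwaygen import (
    AirwayTree,
    FluidProperties,
    assign_generations,
    branch_resistance,
    flow_conservation_error,
    pedley_resistance,
    poiseuille_resistance,
    poiseuille_total_resistance,
    resistance_decomposition,
    solve_flow,
    total_resistance,
)

MU = 1.92e-5


class TestPoiseuille:
    def test_hand_evaluated_value(self):
        # l = 10 mm, d = 2 mm
        expected = 128 * MU * 0.01 / (np.pi * 0.002 ** 4)
        assert poiseuille_resistance(0.01, 0.002, MU) == pytest.approx(expected)
        assert expected == pytest.approx(4.889e5, rel=1e-3)

    def test_doubling_diameter_divides_by_sixteen(self):
        r1 = poiseuille_resistance(0.01, 0.002, MU)
        r2 = poiseuille_resistance(0.01, 0.004, MU)
        assert r1 / r2 == pytest.approx(16.0)

    def test_zero_length_gives_zero(self):
        assert poiseuille_resistance(0.0, 0.002, MU) == 0.0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            poiseuille_resistance(0.01, 0.0, MU)


class TestPedley:
    def test_zero_flow_reduces_to_poiseuille(self):
        rp = poiseuille_resistance(0.01, 0.002, MU)
        assert pedley_resistance(0.01, 0.002, 0.0) == pytest.approx(rp)

    def test_continuity_at_unit_correction(self):
        # pick Q so that Z == 1 exactly, then R == R_p on both sides
        props = FluidProperties()
        l, d = 0.01, 0.002
        # Z = (c/4) sqrt(Re d / l), Re = 4 rho Q / (mu pi d)
        re_star = (4.0 / props.pedley_c) ** 2 * l / d
        q_star = re_star * props.viscosity * np.pi * d / (4 * props.density)
        rp = poiseuille_resistance(l, d, MU)
        assert pedley_resistance(l, d, q_star) == pytest.approx(rp, rel=1e-12)
        assert pedley_resistance(l, d, 0.99 * q_star) == pytest.approx(rp)
        assert pedley_resistance(l, d, 1.01 * q_star) > rp

    def test_hand_evaluated_high_reynolds_value(self):
        # Re = 1000 and d/l = 0.1 -> Z = (1.85/4) * sqrt(100)
        props = FluidProperties()
        d = 0.002
        l = d / 0.1
        q = 1000.0 * props.viscosity * np.pi * d / (4 * props.density)
        z = (1.85 / 4.0) * np.sqrt(1000.0 * d / l)
        rp = poiseuille_resistance(l, d, MU)
        assert pedley_resistance(l, d, q) == pytest.approx(z * rp, rel=1e-12)

    def test_symmetric_in_flow_sign(self):
        assert pedley_resistance(0.01, 0.002, 1e-4) == pytest.approx(
            pedley_resistance(0.01, 0.002, -1e-4))

    def test_never_below_poiseuille(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            l = rng.uniform(1e-3, 0.1)
            d = rng.uniform(2e-4, 0.02)
            q = rng.uniform(0, 2e-3)
            assert pedley_resistance(l, d, q) >= poiseuille_resistance(
                l, d, MU) * (1 - 1e-12)


def _single_tube(radii_mm, z_mm):
    t = AirwayTree()
    path = [t.add_node((0, 0, z), r) for z, r in zip(z_mm, radii_mm)]
    t.add_branch(path, origin="ct")
    return t


class TestBranchResistance:
    def test_uniform_branch_equals_single_tube(self):
        t = _single_tube([1.0] * 5, [0, 2.5, 5.0, 7.5, 10.0])
        expected = poiseuille_resistance(0.01, 0.002, MU)
        assert branch_resistance(t, t.root_branch) == pytest.approx(expected)

    def test_uniform_branch_pedley_subdivision_invariant(self):
        q = 1e-3
        coarse = _single_tube([1.0, 1.0], [0, 10.0])
        fine = _single_tube([1.0] * 9, np.linspace(0, 10, 9))
        rc = branch_resistance(coarse, coarse.root_branch, q, model="pedley")
        rf = branch_resistance(fine, fine.root_branch, q, model="pedley")
        assert rc == pytest.approx(rf, rel=1e-12)
        assert rc == pytest.approx(pedley_resistance(0.01, 0.002, q), rel=1e-12)

    def test_stepped_branch_series_sum(self):
        # two equal-length segments with d and d/2: R = (1 + 16) x base
        t = _single_tube([1.0, 1.0, 0.5, 0.5], [0, 5.0, 5.0 + 1e-9, 10.0])
        base = poiseuille_resistance(0.005, 0.002, MU)
        r = branch_resistance(t, t.root_branch)
        assert r == pytest.approx(17.0 * base, rel=1e-4)

    def test_tapered_branch_matches_refinement_oracle(self):
        rng = np.random.default_rng(1)
        z = np.linspace(0, 20, 6)
        radii = np.linspace(1.3, 1.0, 6) + 0.02 * rng.random(6)
        coarse = _single_tube(radii, z)
        zf = np.linspace(0, 20, 51)
        rf = np.interp(zf, z, radii)
        fine = _single_tube(rf, zf)
        rc = branch_resistance(coarse, coarse.root_branch)
        rfv = branch_resistance(fine, fine.root_branch)
        assert rc == pytest.approx(rfv, rel=0.01)


def _symmetric_bifurcation(d_parent=4.0, d_child=3.0, l_parent=20.0,
                           l_child=15.0):
    t = AirwayTree()
    n0 = t.add_node((0, 0, 0), d_parent / 2)
    n1 = t.add_node((0, 0, l_parent), d_parent / 2)
    root = t.add_branch([n0, n1], origin="ct")
    for s in (-1, 1):
        c = t.add_node((s * l_child * 0.6, 0, l_parent + l_child * 0.8),
                       d_child / 2)
        t.add_branch([n1, c], parent=root, origin="generated")
    # child branch length must equal l_child
    for cid in t.branches[root].children:
        pts = t.path_points(cid)
        assert np.linalg.norm(pts[1] - pts[0]) == pytest.approx(l_child)
    assign_generations(t)
    for cid in t.branches[root].children:
        t.branches[cid].diameter = d_child
    return t


class TestSolver:
    def test_symmetric_bifurcation_matches_closed_form(self):
        t = _symmetric_bifurcation()
        state = solve_flow(t, 1e-3, model="poiseuille")
        r_parent = poiseuille_resistance(0.020, 0.004, MU)
        r_child = poiseuille_resistance(0.015, 0.003, MU)
        expected = r_parent + r_child / 2.0
        assert total_resistance(state) == pytest.approx(expected, rel=1e-10)

    def test_symmetric_tree_flow_split(self, tiny_model=None):
        t = _symmetric_bifurcation()
        state = solve_flow(t, 1e-3, model="poiseuille")
        for cid in t.branches[t.root_branch].children:
            assert state.flow_of(cid) == pytest.approx(0.5e-3, rel=1e-12)

    def test_asymmetric_pedley_matches_scalar_root_finder(self):
        # trachea feeding two unequal tubes: the flow split solves a scalar
        # pressure-balance equation
        t = AirwayTree()
        n0 = t.add_node((0, 0, 0), 9.0)
        n1 = t.add_node((0, 0, 100.0), 9.0)
        root = t.add_branch([n0, n1], origin="ct")
        na = t.add_node((30, 0, 140.0), 6.0)
        nb = t.add_node((-20, 0, 130.0), 4.0)
        ba = t.add_branch([n1, na], parent=root, origin="ct")
        bb = t.add_branch([n1, nb], parent=root, origin="ct")
        assign_generations(t)
        q_in = 1.67e-3
        la = np.linalg.norm([30, 0, 40]) * 1e-3
        lb = np.linalg.norm([-20, 0, 30]) * 1e-3

        def dp(l, d, q):
            return pedley_resistance(l, d, q) * q

        # segment diameters are endpoint-radius sums: 9+6 and 9+4 mm
        f = lambda qa: dp(la, 0.015, qa) - dp(lb, 0.013, q_in - qa)
        qa = brentq(f, 1e-12, q_in - 1e-12, xtol=1e-16)
        state = solve_flow(t, q_in, model="pedley", tol=1e-12)
        assert state.flow_of(ba) == pytest.approx(qa, abs=1e-8 * q_in)

    def test_flow_conservation_on_complete_tree(self, tiny_model):
        tree = tiny_model["tree"]
        state = solve_flow(tree, 0.83e-3, model="pedley")
        assert flow_conservation_error(tree, state) < 1e-8

    def test_pedley_at_least_poiseuille_per_branch(self, tiny_model):
        tree = tiny_model["tree"]
        sp = solve_flow(tree, 1.67e-3, model="poiseuille")
        sd = solve_flow(tree, 1.67e-3, model="pedley")
        assert (sd.resistance >= sp.resistance * (1 - 1e-12)).all()

    def test_total_resistance_nondecreasing_in_flow(self, tiny_model):
        tree = tiny_model["tree"]
        totals = [total_resistance(solve_flow(tree, q * 1e-3, model="pedley"))
                  for q in (0.17, 0.83, 1.67)]
        assert totals[0] <= totals[1] <= totals[2]

    def test_poiseuille_converges_in_one_iteration(self, tiny_model):
        state = solve_flow(tiny_model["tree"], 1e-3, model="poiseuille")
        assert state.iterations == 1

    def test_converged_state_reentry_converges_immediately(self, tiny_model):
        tree = tiny_model["tree"]
        s1 = solve_flow(tree, 0.83e-3, model="pedley")
        s2 = solve_flow(tree, 0.83e-3, model="pedley", initial_flows=s1.flow)
        assert s2.iterations == 1

    def test_halving_all_diameters_scales_poiseuille_16x(self, tiny_model):
        from airwaygen import ConstrictionSpec, apply_constriction
        tree = tiny_model["tree"]
        r0 = poiseuille_total_resistance(tree)
        halved = tree.copy()
        for n in halved.nodes.values():
            n.radius *= 0.5
        for br in halved.branches.values():
            if br.diameter is not None:
                br.diameter *= 0.5
        assert poiseuille_total_resistance(halved) == pytest.approx(
            16.0 * r0, rel=1e-9)

    def test_node_renumbering_invariance(self):
        t1 = _symmetric_bifurcation()
        r1 = poiseuille_total_resistance(t1)
        # rebuild with permuted node ids
        t2 = AirwayTree()
        remap = {}
        for nid, n in sorted(t1.nodes.items(), reverse=True):
            remap[nid] = t2.add_node(n.position, n.radius, node_id=100 - nid)
        for bid in t1.branches_preorder():
            br = t1.branches[bid]
            t2.add_branch([remap[n] for n in br.node_path],
                          parent=br.parent, origin=br.origin)
            t2.branches[bid].diameter = br.diameter
        assign_generations(t2)
        assert poiseuille_total_resistance(t2) == pytest.approx(r1, rel=1e-12)

    def test_zero_inlet_flow_rejected_for_total(self, tiny_model):
        state = solve_flow(tiny_model["tree"], 0.0, model="pedley")
        with pytest.raises(ValueError, match="zero inlet flow"):
            total_resistance(state)


class TestDecomposition:
    def test_fractions_sum_to_one(self, tiny_model):
        tree = tiny_model["tree"]
        state = solve_flow(tree, 0.83e-3, model="pedley")
        dec = resistance_decomposition(tree, state)
        assert sum(dec.per_generation_fraction.values()) == pytest.approx(
            1.0, abs=1e-9)
        assert 0.0 <= dec.generated_fraction <= 1.0

    def test_all_ct_tree_has_zero_generated_fraction(self, tiny_anatomy):
        _, central = tiny_anatomy
        central = central.copy()
        assign_generations(central)
        state = solve_flow(central, 1e-3, model="poiseuille")
        dec = resistance_decomposition(central, state)
        assert dec.generated_fraction == 0.0

    def test_symmetric_tree_fraction_equals_pressure_drop_share(self):
        t = _symmetric_bifurcation()
        state = solve_flow(t, 1e-3, model="poiseuille")
        dec = resistance_decomposition(t, state)
        p_in = state.inlet_pressure
        r_parent = poiseuille_resistance(0.020, 0.004, MU)
        dp_parent = r_parent * 1e-3
        assert dec.per_generation_fraction[0] == pytest.approx(
            dp_parent / p_in, rel=1e-9)
        assert dec.per_generation_fraction[1] == pytest.approx(
            1 - dp_parent / p_in, rel=1e-9)
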