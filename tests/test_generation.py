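import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from airwaygen import (
    GenerationConfig,
    GeometryError,
    adaptive_threshold,
    assign_seeds_to_apices,
    check_terminal,
    clamp_branching_angle,
    generate_complete_tree,
    grow_point,
    make_seed_grid,
    points_inside_lobe,
    split_by_plane,
    tree_bytes,
)
from conftest import make_cube_surface


class TestAdaptiveThreshold:
    def test_direct_arithmetic(self):
        assert adaptive_threshold(300.0, 12.0, 10) == 180.0

    def test_floor_branch(self):
        assert adaptive_threshold(300.0, 12.0, 40) == 5.0

    def test_zeroth_generation_returns_diagonal(self):
        assert adaptive_threshold(300.0, 12.0, 0) == 300.0

    @given(v_b=st.floats(10, 1000), n=st.integers(0, 100))
    @settings(deadline=None)
    def test_monotone_nonincreasing_in_generation(self, v_b, n):
        d_l = v_b / 25.0
        assert adaptive_threshold(v_b, d_l, n + 1) <= adaptive_threshold(v_b, d_l, n)
        assert adaptive_threshold(v_b, d_l, n) >= 5.0


class TestSeedGrid:
    def test_spacing_is_cube_root_of_acinar_volume(self):
        cube = make_cube_surface(side=60.0)
        grid = make_seed_grid(cube, 187.0)
        assert grid.spacing == pytest.approx(187.0 ** (1 / 3))
        assert grid.spacing == pytest.approx(5.718, abs=1e-3)

    def test_count_tracks_volume_over_acinar_volume(self):
        # cube of volume 187,000 mm^3 should hold about 1000 seeds
        side = (187_000.0) ** (1 / 3)
        cube = make_cube_surface(side=side)
        grid = make_seed_grid(cube, 187.0)
        assert abs(len(grid.points) - 1000) <= 150
        assert points_inside_lobe(grid.points, cube).all()

    def test_degenerate_lobe_rejected(self):
        tiny = make_cube_surface(side=3.0)
        with pytest.raises(GeometryError):
            make_seed_grid(tiny, 187.0)


class TestAssignment:
    def test_all_within_threshold_assigned_to_single_apex(self):
        apices = np.array([[0.0, 0, 0]])
        seeds = np.array([[1.0, 0, 0], [0, 2.0, 0]])
        nearest, ok = assign_seeds_to_apices(apices, seeds, threshold=5.0)
        assert nearest.tolist() == [0, 0] and ok.all()

    def test_boundary_seed_at_exact_threshold_is_assigned(self):
        apices = np.array([[0.0, 0, 0]])
        seeds = np.array([[3.0, 0, 0]])
        _, ok = assign_seeds_to_apices(apices, seeds, threshold=3.0)
        assert ok.all()
        _, ok = assign_seeds_to_apices(apices, seeds, threshold=2.999)
        assert not ok.any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        apices = rng.uniform(0, 50, size=(3, 3))
        seeds = rng.uniform(0, 50, size=(50, 3))
        nearest, ok = assign_seeds_to_apices(apices, seeds, threshold=30.0)
        d = np.linalg.norm(seeds[:, None] - apices[None], axis=2)
        assert (nearest == d.argmin(axis=1)).all()
        assert (ok == (d.min(axis=1) <= 30.0)).all()

    def test_kdtree_path_agrees_with_dense_path(self):
        rng = np.random.default_rng(12)
        apices = rng.uniform(0, 50, size=(1100, 3))
        seeds = rng.uniform(0, 50, size=(1000, 3))  # forces the KD-tree route
        nearest_kd, ok_kd = assign_seeds_to_apices(apices, seeds, threshold=10.0)
        d = np.linalg.norm(seeds[:, None] - apices[None], axis=2)
        assert (nearest_kd == d.argmin(axis=1)).all()
        assert (ok_kd == (d.min(axis=1) <= 10.0)).all()


class TestSplitByPlane:
    P0 = np.array([0.0, 0.0, -5.0])
    P1 = np.array([0.0, 0.0, 0.0])

    def test_symmetric_cloud_splits_evenly(self):
        pts = np.array([[1, 1, 1], [1, -1, 1], [-1, 1, 1], [-1, -1, 1]], float)
        a, b = split_by_plane(pts, self.P0, self.P1)
        assert {len(a), len(b)} == {2}
        assert sorted(np.concatenate([a, b]).tolist()) == [0, 1, 2, 3]

    def test_lopsided_cloud(self):
        pts = np.array([[10, 1, 1], [10, 2, 1], [10, 1.5, 2], [-30, 0, 1]], float)
        a, b = split_by_plane(pts, self.P0, self.P1)
        assert sorted((len(a), len(b))) == [1, 3]

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_partition_properties_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(int(rng.integers(2, 40)), 3))
        a, b = split_by_plane(pts, self.P0, self.P1)
        assert len(a) > 0 and len(b) > 0
        union = sorted(np.concatenate([a, b]).tolist())
        assert union == list(range(len(pts)))  # disjoint and exhaustive

    def test_collinear_degeneracy_uses_fallback_plane(self):
        # centroid on the parent axis: fallback splits along the axis
        pts = np.array([[0, 0, 2.0], [0, 0, 6.0]])
        a, b = split_by_plane(pts, self.P0, self.P1)
        assert len(a) == 1 and len(b) == 1


class TestGrowth:
    def test_forty_percent_extension(self):
        end = grow_point([0.0, 0, 0], [10.0, 0, 0], 0.40)
        assert np.allclose(end, [4.0, 0, 0])

    def test_degenerate_centroid_raises(self):
        with pytest.raises(GeometryError):
            grow_point([1.0, 2, 3], [1.0, 2, 3], 0.4)

    def test_unit_fraction_reaches_centroid(self):
        end = grow_point([0.0, 0, 0], [3.0, 4, 0], 1.0)
        assert np.allclose(end, [3.0, 4, 0])

    def test_angle_clamp_only_affects_wide_angles(self):
        u = np.array([0.0, 0, 1])
        apex = np.zeros(3)
        gentle = np.array([0.5, 0, 1.0])
        assert np.allclose(
            clamp_branching_angle(u, apex, gentle, 60.0), gentle)
        wide = np.array([5.0, 0, -1.0])
        clamped = clamp_branching_angle(u, apex, wide, 60.0)
        assert np.linalg.norm(clamped) == pytest.approx(np.linalg.norm(wide))
        cos = clamped @ u / np.linalg.norm(clamped)
        assert np.degrees(np.arccos(cos)) == pytest.approx(60.0, abs=1e-9)

    def test_terminal_rules(self):
        assert check_terminal(1.9, 5)  # reach below the prescribed length
        assert check_terminal(8.0, 1)  # single-point set
        assert not check_terminal(8.0, 3)

    def test_two_seeds_one_apex_hand_trace(self):
        # one apex with two seeds: split 1+1, grow towards each seed, both
        # children single-point terminal
        apex_prox = np.array([0.0, 0, -10.0])
        apex_dist = np.array([0.0, 0, 0.0])
        seeds = np.array([[-5.0, 0, 8.0], [5.0, 0, 8.0]])
        nearest, ok = assign_seeds_to_apices(apex_dist[None], seeds, 100.0)
        assert ok.all()
        a, b = split_by_plane(seeds, apex_prox, apex_dist)
        assert len(a) == 1 and len(b) == 1
        for side in (a, b):
            end = grow_point(apex_dist, seeds[side[0]], 0.40)
            reach = np.linalg.norm(seeds[side[0]] - apex_dist)
            assert check_terminal(reach, len(side))
            assert np.linalg.norm(end - apex_dist) == pytest.approx(0.4 * reach)


class TestCompleteTree:
    def test_seed_conservation_exact(self, tiny_model):
        stats = tiny_model["stats"]
        for lobe in stats.initial_seeds:
            assert (stats.consumed[lobe] + stats.discarded[lobe]
                    == stats.initial_seeds[lobe])

    def test_terminal_count_bounded_by_seed_count(self, tiny_model):
        tree, stats = tiny_model["tree"], tiny_model["stats"]
        n_generated_terminals = sum(
            1 for b in tree.terminal_branches()
            if tree.branches[b].origin == "generated")
        # a handful of terminals may close after the last seed is consumed
        assert n_generated_terminals <= 1.02 * sum(stats.initial_seeds.values())

    def test_tree_is_bifurcating_and_tagged(self, tiny_model):
        tree = tiny_model["tree"]
        tree.validate()
        for br in tree.branches.values():
            if br.origin == "generated":
                assert br.lobe in ("RUL", "RML", "RLL", "LUL", "LLL")

    def test_generated_nodes_inside_host_lobe(self, tiny_model):
        tree, lobes = tiny_model["tree"], tiny_model["lobes"]
        by_label = {lo.label: lo for lo in lobes}
        pts = {}
        for br in tree.branches.values():
            if br.origin == "generated":
                pts.setdefault(br.lobe, []).append(
                    tree.nodes[br.node_path[-1]].position)
        for label, p in pts.items():
            inside = points_inside_lobe(np.array(p), by_label[label])
            assert inside.mean() > 0.995

    def test_mean_branch_length_decreases_with_generation(self, tiny_model):
        tree = tiny_model["tree"]
        by_gen = {}
        for bid, br in tree.branches.items():
            if br.origin == "generated":
                by_gen.setdefault(br.generation, []).append(
                    tree.branch_length(bid))
        gens = sorted(g for g in by_gen if len(by_gen[g]) >= 5)
        means = [np.mean(by_gen[g]) for g in gens]
        first, second = means[:len(means) // 2], means[len(means) // 2:]
        assert np.mean(first) > np.mean(second)

    def test_fixed_seed_reproduces_tree_exactly(self, tiny_anatomy):
        lobes, central = tiny_anatomy
        cfg = GenerationConfig(rng_seed=3)
        t1, _ = generate_complete_tree(central, lobes, cfg)
        t2, _ = generate_complete_tree(central, lobes, cfg)
        assert tree_bytes(t1) == tree_bytes(t2)

    def test_missing_central_tip_in_lobe_is_an_error(self, tiny_anatomy):
        from airwaygen import GenerationError
        lobes, central = tiny_anatomy
        # offset one lobe far away so it cannot contain any tip
        far = type(lobes[0])(lobes[0].vertices + 500.0, lobes[0].triangles,
                             label="far")
        with pytest.raises(GenerationError, match="no central airway tip"):
            generate_complete_tree(central, [far], GenerationConfig(rng_seed=0))
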