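"""Morphology: SWC I/O, morphometry, labeling, discretization, generator."""

import numpy as np
import pytest

from mbsim.cable import BiophysicsParams
from mbsim.morphology import (DEFAULT_GGN_TARGETS, CALYX_REGIONS, Morphology,
                              MorphologyError, MorphometryStats, RegionLabel,
                              compartmentalize, generate_synthetic_ggn,
                              label_regions, load_swc, morphometry, save_swc)


def make_tree(parents, xyz, radius=1.0, stype=5):
    n = len(parents)
    return Morphology(
        ids=np.arange(1, n + 1),
        parent_index=np.asarray(parents),
        xyz=np.asarray(xyz, dtype=float),
        radius=np.full(n, float(radius)),
        struct_type=np.full(n, stype),
    )


class TestSWC:
    def test_minimal_three_node_file(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("# comment\n1 1 0 0 0 5 -1\n2 5 10 0 0 1 1\n3 5 0 10 0 1 1\n")
        m = load_swc(p)
        assert m.n_nodes == 3
        assert morphometry(m).n_branch_points == 1

    def test_round_trip_identity(self, tmp_path):
        m = generate_synthetic_ggn(seed=3)
        path = tmp_path / "g.swc"
        save_swc(m, path)
        m2 = load_swc(path)
        assert m2.n_nodes == m.n_nodes
        # ids are remapped to contiguous 1..N but the tree is isomorphic:
        # same sorted degree sequence, segment lengths and radii
        np.testing.assert_allclose(sorted(m2.segment_lengths()),
                                   sorted(m.segment_lengths()), atol=1e-3)
        np.testing.assert_allclose(sorted(m2.radius), sorted(m.radius),
                                   atol=1e-3)
        assert list(m2.ids) == list(range(1, m.n_nodes + 1))
        # second round trip is exact
        path2 = tmp_path / "g2.swc"
        save_swc(m2, path2)
        assert path.read_text() == path2.read_text()

    def test_orphan_node_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 5 10 0 0 1 99\n")
        with pytest.raises(MorphologyError):
            load_swc(p)

    def test_non_positive_radius_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 0 -1\n")
        with pytest.raises(MorphologyError):
            load_swc(p)

    def test_two_roots_rejected(self):
        with pytest.raises(MorphologyError):
            make_tree([-1, -1], [[0, 0, 0], [1, 0, 0]])


class TestMorphometry:
    def test_straight_chain(self):
        xyz = [[0, 0, 0], [50, 0, 0], [100, 0, 0]]
        m = make_tree([-1, 0, 1], xyz)
        s = morphometry(m)
        assert s.total_length == pytest.approx(100.0)
        assert s.n_branch_points == 0
        assert s.max_path_length == pytest.approx(100.0)
        assert s.max_euclidean == pytest.approx(100.0)

    def test_y_tree_tip_to_tip_path(self):
        xyz = [[0, 0, 0], [0, 0, 100], [100, 0, 100], [-100, 0, 100]]
        m = make_tree([-1, 0, 1, 1], xyz)
        s = morphometry(m)
        assert s.max_path_length == pytest.approx(200.0)
        assert s.total_length == pytest.approx(300.0)
        assert s.n_branch_points == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        m = generate_synthetic_ggn(seed=5)
        s = morphometry(m)
        perm = rng.permutation(m.n_nodes)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(m.n_nodes)
        new_parent = np.where(m.parent_index[perm] >= 0,
                              inv[np.maximum(m.parent_index[perm], 0)], -1)
        m2 = Morphology(ids=m.ids[perm], parent_index=new_parent,
                        xyz=m.xyz[perm], radius=m.radius[perm],
                        struct_type=m.struct_type[perm])
        s2 = morphometry(m2)
        assert s2.total_length == pytest.approx(s.total_length)
        assert s2.max_path_length == pytest.approx(s.max_path_length)
        assert s2.n_branch_points == s.n_branch_points


class TestSyntheticGGN:
    def test_total_length_within_ten_percent(self):
        s = morphometry(generate_synthetic_ggn(seed=1))
        assert 58_500 <= s.total_length <= 71_500

    def test_deterministic_per_seed(self, tmp_path):
        a, b = generate_synthetic_ggn(seed=11), generate_synthetic_ggn(seed=11)
        np.testing.assert_array_equal(a.xyz, b.xyz)
        np.testing.assert_array_equal(a.radius, b.radius)

    def test_diameters_taper_from_twenty_micron(self):
        m = generate_synthetic_ggn(seed=1)
        assert 2 * m.radius.max() == pytest.approx(20.0, rel=0.05)
        assert 2 * m.radius.min() <= 1.0

    def test_calyces_hold_majority_of_terminals(self, ggn_model):
        term = ggn_model.terminal_mask()
        calyx = np.isin(ggn_model.region, [int(r) for r in CALYX_REGIONS])
        assert (term & calyx).sum() >= 0.5 * term.sum()

    def test_calyx_reachable_without_alpha_lobe(self):
        m = generate_synthetic_ggn(seed=1)
        children = m.children_lists()
        order = m.topological_order()
        alpha = int(RegionLabel.ALPHA_LOBE)
        # walk from root, never entering alpha-lobe nodes
        seen = set()
        stack = [int(order[0])]
        while stack:
            i = stack.pop()
            if int(m.region[i]) == alpha:
                continue
            seen.add(i)
            stack.extend(children[i])
        calyx_nodes = np.flatnonzero(
            np.isin(m.region, [int(r) for r in CALYX_REGIONS]))
        assert set(calyx_nodes.tolist()) <= seen

    def test_negative_targets_rejected(self):
        bad = MorphometryStats(-1.0, 2000.0, 1000.0, 1, 20.0)
        with pytest.raises(ValueError):
            generate_synthetic_ggn(seed=1, targets=bad)


class TestLabeling:
    def test_builtin_labels_pass_through(self):
        m = generate_synthetic_ggn(seed=2)
        region_before = m.region.copy()
        np.testing.assert_array_equal(label_regions(m).region, region_before)

    def test_custom_code_mapping(self):
        m = make_tree([-1, 0, 0], [[0, 0, 0], [10, 0, 0], [0, 10, 0]], stype=7)
        m.region = None
        out = label_regions(m, {7: RegionLabel.CALYX_LATERAL})
        assert set(out.region) == {int(RegionLabel.CALYX_LATERAL)}

    def test_unlabeled_code_raises(self):
        m = make_tree([-1, 0], [[0, 0, 0], [10, 0, 0]], stype=42)
        m.region = None
        with pytest.raises(MorphologyError):
            label_regions(m, {1: RegionLabel.SOMA})


class TestCompartmentalize:
    def test_single_short_cylinder_is_one_compartment(self, bio):
        m = make_tree([-1, 0], [[0, 0, 0], [30, 0, 0]], radius=2.0)
        model = compartmentalize(m, bio)
        # root compartment + one for the 30 um segment (<< 0.1 lambda)
        assert model.n_comp == 2

    def test_membrane_area_conserved(self, ggn_morph, ggn_model):
        seg = ggn_morph.segment_lengths()
        analytic = float(np.sum(np.pi * (2 * ggn_morph.radius * 1e-4)
                                * (seg * 1e-4)))
        assert ggn_model.area.sum() == pytest.approx(analytic, rel=0.01)

    @pytest.mark.parametrize("seed", [2, 9])
    def test_halving_rule_increases_resolution(self, seed, bio):
        m = generate_synthetic_ggn(
            seed=seed,
            targets=MorphometryStats(5_000.0, 2_000.0, 1_000.0, 20, 20.0),
            seg_um=400.0)
        coarse = compartmentalize(m, bio, max_elec_len=0.1)
        fine = compartmentalize(m, bio, max_elec_len=0.05)
        n_sections = m.n_nodes - 1
        assert fine.n_comp >= 2 * coarse.n_comp - n_sections - 1
        assert fine.area.sum() == pytest.approx(coarse.area.sum(), rel=0.01)

    def test_region_labels_inherited(self, ggn_model):
        assert set(np.unique(ggn_model.region)) == {
            int(r) for r in RegionLabel}

    def test_hines_ordering(self, ggn_model):
        assert np.all(ggn_model.parent < np.arange(ggn_model.n_comp))
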