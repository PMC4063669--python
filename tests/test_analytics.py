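"""Coexpression, WPGMA, entropy, robustness and expansion analytics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from atlasforge import (
    CellProfileTable, cluster_cells, cluster_genes, cophenetic_correlation,
    cut_tree, distance_matrix_correlation, entropy,
    expansion_rate_ratio, generate_profile_population, pair_overlap,
    perturb_full_random, perturb_one_cell, robustness_experiment,
    topology_trajectory, wpgma,
)
from atlasforge.evaluation import wpgma_reference


def _table(g, genes=None):
    g = np.asarray(g, dtype=np.int8)
    genes = genes or [f"g{i}" for i in range(g.shape[1])]
    rng = np.random.default_rng(0)
    return CellProfileTable(rng.uniform(0, 100, (g.shape[0], 3)), genes, g)


class TestPairOverlap:
    def test_self_overlap_is_total(self):
        t = _table(np.array([[1, 1], [1, 0], [0, 0]]))
        ov = pair_overlap(t, "g0", "g0")
        assert ov.frac_a == ov.frac_b == ov.dice == 1.0

    def test_disjoint_sets_have_zero_overlap(self):
        t = _table(np.array([[1, 0], [0, 1], [0, 1]]))
        ov = pair_overlap(t, "g0", "g1")
        assert ov.n_ab == 0 and ov.dice == 0.0

    def test_worked_example_fractions(self):
        g = np.zeros((25, 2), dtype=int)
        g[:10, 0] = 1
        g[5:25, 1] = 1
        ov = pair_overlap(_table(g), "g0", "g1")
        assert (ov.n_a, ov.n_b, ov.n_ab) == (10, 20, 5)
        assert ov.frac_a == pytest.approx(0.5)
        assert ov.frac_b == pytest.approx(0.25)
        assert ov.dice == pytest.approx(1 / 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 12 - 1), st.integers(0, 2 ** 12 - 1))
    def test_dice_symmetry_and_bounds(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(12)])
        b = np.array([(bits_b >> i) & 1 for i in range(12)])
        t = _table(np.stack([a, b], axis=1))
        ab = pair_overlap(t, "g0", "g1")
        ba = pair_overlap(t, "g1", "g0")
        assert ab.dice == ba.dice
        assert 0.0 <= ab.dice <= 1.0
        if a.sum():
            assert pair_overlap(t, "g0", "g0").dice == 1.0


class TestTopologyTrajectory:
    def test_inclusion_lands_bottom_right(self):
        g = np.zeros((20, 2), dtype=int)
        g[:5, 0] = 1          # A strictly inside B
        g[:15, 1] = 1
        df = topology_trajectory([pair_overlap(_table(g), "g0", "g1")])
        assert df.relationship[0] == "a_in_b"
        assert df.x_frac_a[0] == 1.0
        assert df.y_frac_b[0] == pytest.approx(5 / 15)

    def test_staged_path_from_inclusion_to_exclusion(self):
        tables = []
        for overlap in (5, 2, 0):  # A (5 cells) slides out of B
            g = np.zeros((30, 2), dtype=int)
            g[10:15, 0] = 1
            g[:10 + overlap, 1] = 1
            tables.append(_table(g))
        df = topology_trajectory(
            [pair_overlap(t, "g0", "g1") for t in tables])
        assert df.relationship.tolist() == ["a_in_b", "intersection", "exclusion"]


class TestWpgma:
    def test_two_leaves(self):
        tree = wpgma(np.array([[0.0, 5.0], [5.0, 0.0]]))
        assert tree.merges == [(0, 1, 5.0, 2)]

    def test_hand_example_merge_heights(self):
        pts = np.array([0.0, 1.0, 4.0, 5.0])
        tree = wpgma(np.abs(pts[:, None] - pts[None, :]))
        assert [m[2] for m in tree.merges] == [1.0, 1.0, 4.0]
        assert tree.merges[0][:2] == (0, 1)
        assert tree.merges[1][:2] == (2, 3)

    def test_ultrametric_input_reproduced_exactly(self):
        # tree: (0,1)@2, (2,3)@3, root@5 -> its cophenetic matrix is an
        # ultrametric; WPGMA must reconstruct it with zero distortion
        d = squareform(np.array([2.0, 5.0, 5.0, 5.0, 5.0, 3.0]))
        tree = wpgma(d)
        np.testing.assert_allclose(tree.cophenetic(), squareform(d))
        assert cophenetic_correlation(tree, d) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_weighted_linkage(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        pts = rng.uniform(0, 10, (n, 4))
        d = pdist(pts)
        mine = wpgma(d).to_scipy()
        ref = linkage(d, method="weighted")
        np.testing.assert_allclose(mine[:, 2], ref[:, 2], atol=1e-9)
        np.testing.assert_allclose(mine[:, 3], ref[:, 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_recurrence_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        tri = np.round(rng.uniform(0.1, 5.0, (n, n)), 1)  # coarse -> ties
        d = np.triu(tri, 1)
        d = d + d.T
        assert wpgma(d).merges == [
            (a, b, pytest.approx(h), s) for a, b, h, s in wpgma_reference(d)]

    def test_nan_distances_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            wpgma(d)


class TestClusterCells:
    def test_two_pure_profiles_split_perfectly(self):
        g = np.array([[1, 0]] * 10 + [[0, 1]] * 15)
        idx, labels, _ = cluster_cells(_table(g), k=2)
        assert len(idx) == 25
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_all_zero_cells_excluded_by_default(self):
        g = np.array([[1, 0]] * 5 + [[0, 0]] * 5 + [[0, 1]] * 5)
        idx, labels, _ = cluster_cells(_table(g), k=2)
        assert len(idx) == 10
        assert 5 not in idx

    def test_invariant_to_cell_order(self, rng):
        g = rng.integers(0, 2, (40, 4))
        g[g.sum(axis=1) == 0, 0] = 1
        t = _table(g)
        idx_a, lab_a, _ = cluster_cells(t, k=3)
        perm = rng.permutation(40)
        t2 = CellProfileTable(t.positions[perm], t.genes, g[perm])
        idx_b, lab_b, _ = cluster_cells(t2, k=3)
        # compare partitions through pair-membership matrices
        def comembership(idx, lab, order):
            m = np.full(40, -1)
            m[idx] = lab
            m = m[np.argsort(order)] if order is not None else m
            return np.equal.outer(m, m)
        np.testing.assert_array_equal(
            comembership(idx_a, lab_a, None),
            comembership(perm[idx_b], lab_b, None))


class TestClusterGenes:
    def test_duplicate_columns_merge_first_at_zero(self, rng):
        a = rng.integers(0, 2, 50)
        c = rng.integers(0, 2, 50)
        t = _table(np.stack([a, a, c], axis=1), genes=["a", "b", "c"])
        tree, names = cluster_genes([t])
        assert tree.merges[0][:3] == (0, 1, 0.0)

    def test_complementary_patterns_at_maximal_distance(self):
        a = np.array([1, 0] * 30)
        t = _table(np.stack([a, 1 - a], axis=1), genes=["a", "b"])
        tree, _ = cluster_genes([t])
        assert tree.merges[0][2] == pytest.approx(np.sqrt(60))

    def test_mismatched_gene_lists_rejected(self):
        t1 = _table(np.zeros((5, 2), int), genes=["a", "b"])
        t2 = _table(np.zeros((5, 2), int), genes=["a", "c"])
        with pytest.raises(ValueError, match="same gene list"):
            cluster_genes([t1, t2])


class TestEntropy:
    def test_single_profile_has_zero_entropy(self):
        rep = entropy(np.tile([1, 0, 1], (20, 1)))
        assert rep.H == 0.0
        assert rep.n_profiles_used == 1

    def test_half_quarter_quarter_distribution(self):
        rep = entropy(np.array([[0, 0], [0, 0], [0, 1], [1, 0]]))
        assert rep.H == pytest.approx(1.5)
        np.testing.assert_allclose(sorted(rep.probabilities), [0.25, 0.25, 0.5])

    def test_uniform_profiles_attain_the_maximum(self):
        table = generate_profile_population(
            {format(i, "04b"): 2 for i in range(16)})
        rep = entropy(table)
        assert rep.H == pytest.approx(4.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 7), min_size=1, max_size=64))
    def test_bounds_and_contribution_sum(self, codes):
        g = np.array([[(c >> b) & 1 for b in range(3)] for c in codes])
        rep = entropy(g)
        assert 0.0 <= rep.H <= 3.0 + 1e-12
        assert rep.contributions.sum() == pytest.approx(rep.H)
        assert rep.probabilities.sum() == pytest.approx(1.0)
        assert rep.profiles_for_60pct <= rep.profiles_for_75pct <= rep.profiles_for_90pct

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.empty((0, 3)))


class TestCorrelations:
    def test_hand_example_cophenetic(self):
        pts = np.array([0.0, 1.0, 4.0, 5.0])
        d = np.abs(pts[:, None] - pts[None, :])
        tree = wpgma(d)
        assert cophenetic_correlation(tree, d) == pytest.approx(12 / np.sqrt(168))

    def test_constant_distances_are_undefined(self):
        d = np.full((4, 4), 3.0)
        np.fill_diagonal(d, 0.0)
        tree = wpgma(d)
        with pytest.raises(ValueError, match="zero variance"):
            cophenetic_correlation(tree, d)

    def test_distance_matrix_correlation_affine_invariance(self, rng):
        d1 = pdist(rng.uniform(size=(10, 3)))
        assert distance_matrix_correlation(d1, d1) == pytest.approx(1.0)
        assert distance_matrix_correlation(d1, 2.5 * d1 + 1.0) == pytest.approx(1.0)

    def test_matches_manual_pearson(self, rng):
        d1 = pdist(rng.uniform(size=(8, 3)))
        d2 = pdist(rng.uniform(size=(8, 3)))
        expected = np.corrcoef(d1, d2)[0, 1]
        assert distance_matrix_correlation(d1, d2) == pytest.approx(expected)


class TestRobustness:
    def test_unperturbed_table_scores_perfectly(self, rng):
        g = rng.integers(0, 2, (60, 4))
        t = _table(g)
        df = robustness_experiment(t, {"same": t.with_G(g.copy())})
        row = df.iloc[0]
        assert row.delta_H_bits == 0.0
        assert row.distance_matrix_r == pytest.approx(1.0)

    def test_one_cell_flip_obeys_the_analytic_entropy_bound(self, rng):
        # moving one cell between profiles changes two counts by one each:
        # |ΔH| ≤ 2·log2(C)/C + 2/C bits
        for _ in range(10):
            c = int(rng.integers(20, 200))
            codes = rng.integers(0, 8, c)
            g = np.array([[(x >> b) & 1 for b in range(3)] for x in codes])
            t = _table(g)
            flipped = perturb_one_cell(t, rng)
            dh = abs(entropy(flipped).H - entropy(t).H)
            assert dh <= 2 * np.log2(c) / c + 2 / c + 1e-12

    def test_full_randomization_degrades_more_than_one_flip(self):
        table = generate_profile_population(
            {"1000": 60, "0100": 60, "0010": 60, "0001": 70})
        rng = np.random.default_rng(1)
        report = robustness_experiment(table, {
            "one-cell": perturb_one_cell(table, rng),
            "random": perturb_full_random(table, rng),
        })
        one = report[report.perturbation == "one-cell"].iloc[0]
        rnd = report[report.perturbation == "random"].iloc[0]
        assert abs(rnd.delta_H_bits) > abs(one.delta_H_bits)
        assert rnd.cophenetic_r < one.cophenetic_r
        assert rnd.distance_matrix_r < one.distance_matrix_r


class TestExpansionRateRatio:
    def test_sustained_expression_gives_ratio_one(self):
        counts = pd.DataFrame([[10, 20, 40]], index=["g"], columns=["t0", "t1", "t2"])
        out = expansion_rate_ratio(counts, [100, 200, 400])
        np.testing.assert_allclose(out.to_numpy(), 1.0)

    def test_constant_counts_under_proliferation_fall_below_one(self):
        counts = pd.DataFrame([[30, 30]], index=["g"], columns=["t0", "t1"])
        out = expansion_rate_ratio(counts, [100, 180])
        assert out.iloc[0, 0] == pytest.approx(100 / 180)

    def test_fixture_matches_hand_computation(self):
        counts = pd.DataFrame([[12, 18], [40, 30]], index=["a", "b"],
                              columns=["t0", "t1"])
        out = expansion_rate_ratio(counts, [200, 300])
        assert out.loc["a", "t0->t1"] == pytest.approx((18 / 12) / (300 / 200))
        assert out.loc["b", "t0->t1"] == pytest.approx((30 / 40) / (300 / 200))
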