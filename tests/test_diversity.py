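"""Alpha/beta diversity against closed forms, brute force and scikit-bio."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.diversity.alpha import faith_pd as skbio_faith_pd
from skbio.diversity.beta import weighted_unifrac as skbio_weighted_unifrac
from skbio.stats.distance import permanova as skbio_permanova

from gutshift import (alpha_diversity, faith_pd, generate_tree, pairwise_group_tests,
                      permanova, richness, shannon, weighted_unifrac,
                      weighted_unifrac_matrix)


def brute_force_faith_pd(tree, present_leaves):
    """Sum lengths over the union of root paths of present leaves."""
    edges = set()
    for name in present_leaves:
        node = tree.find(name)
        while node.parent is not None:
            edges.add(id(node))
            node = node.parent
    total = 0.0
    for node in tree.postorder(include_self=False):
        if id(node) in edges:
            total += node.length
    return total


def brute_force_unifrac(tree, taxa, u, v):
    """Per-branch summation with descendant sets found by direct traversal."""
    u = np.asarray(u, float) / np.sum(u)
    v = np.asarray(v, float) / np.sum(v)
    idx = {t: i for i, t in enumerate(taxa)}
    num = den = 0.0
    for node in tree.postorder(include_self=False):
        leaves = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        a = sum(u[idx[n]] for n in leaves if n in idx)
        b = sum(v[idx[n]] for n in leaves if n in idx)
        num += node.length * abs(a - b)
        den += node.length * (a + b)
    return num / den


class TestShannonRichness:
    def test_closed_forms(self):
        assert shannon([7]) == 0.0
        assert shannon([3, 3, 3, 3]) == pytest.approx(np.log(4))
        assert shannon([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_richness(self):
        assert richness([0, 0, 0]) == 0
        assert richness([0, 5, 0]) == 1


class TestFaithPD:
    def test_single_leaf_is_root_path(self, small_tree):
        taxa = [t.name for t in small_tree.tips()]
        counts = np.zeros(len(taxa))
        counts[2] = 1
        expected = brute_force_faith_pd(small_tree, [taxa[2]])
        assert faith_pd(counts, small_tree, taxa=taxa) == pytest.approx(expected)

    def test_all_present_equals_total_branch_length(self, small_tree):
        taxa = [t.name for t in small_tree.tips()]
        total = sum(n.length for n in small_tree.postorder(include_self=False))
        assert faith_pd(np.ones(len(taxa)), small_tree, taxa=taxa) == pytest.approx(total)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_and_skbio(self, seed):
        rng = np.random.default_rng(seed)
        tree = generate_tree(int(rng.integers(3, 9)), seed=seed)
        taxa = [t.name for t in tree.tips()]
        counts = rng.integers(0, 3, size=len(taxa))
        if counts.sum() == 0:
            counts[0] = 1
        present = [t for t, c in zip(taxa, counts) if c > 0]
        mine = faith_pd(counts, tree, taxa=taxa)
        assert mine == pytest.approx(brute_force_faith_pd(tree, present), abs=1e-12)
        assert mine == pytest.approx(
            skbio_faith_pd(counts, taxa=taxa, tree=tree), abs=1e-9)

    def test_monotone_in_presence(self, small_tree, rng):
        taxa = [t.name for t in small_tree.tips()]
        counts = rng.integers(0, 2, size=len(taxa))
        counts[0] = 0
        counts[1] = 1
        pd0 = faith_pd(counts, small_tree, taxa=taxa)
        counts[0] = 1
        assert faith_pd(counts, small_tree, taxa=taxa) >= pd0

    def test_missing_taxon_named(self, small_tree):
        with pytest.raises(ValueError, match="ASV_9999"):
            faith_pd([1], small_tree, taxa=["ASV_9999"])


class TestWeightedUnifrac:
    def test_identical_rows_zero(self, small_tree, rng):
        taxa = [t.name for t in small_tree.tips()]
        u = rng.integers(1, 10, size=len(taxa))
        assert weighted_unifrac(u, u, small_tree, taxa=taxa) == pytest.approx(0.0)

    def test_two_leaf_disjoint_is_one(self):
        tree = generate_tree(2, seed=0)
        taxa = [t.name for t in tree.tips()]
        assert weighted_unifrac([10, 0], [0, 7], tree, taxa=taxa) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_and_skbio(self, seed):
        rng = np.random.default_rng(1000 + seed)
        tree = generate_tree(int(rng.integers(3, 9)), seed=seed)
        taxa = [t.name for t in tree.tips()]
        u = rng.integers(0, 10, size=len(taxa)); u[0] += 1
        v = rng.integers(0, 10, size=len(taxa)); v[-1] += 1
        mine = weighted_unifrac(u, v, tree, taxa=taxa)
        assert mine == pytest.approx(brute_force_unifrac(tree, taxa, u, v), abs=1e-12)
        assert mine == pytest.approx(
            skbio_weighted_unifrac(u, v, taxa=taxa, tree=tree, normalized=True),
            abs=1e-9)
        assert 0.0 <= mine <= 1.0
        assert mine == pytest.approx(weighted_unifrac(v, u, tree, taxa=taxa))

    def test_matrix_agrees_with_pairwise(self, small_tree, rng):
        taxa = [t.name for t in small_tree.tips()]
        table = pd.DataFrame(rng.integers(0, 10, size=(5, len(taxa))) + 1,
                             columns=taxa)
        mat = weighted_unifrac_matrix(table, small_tree)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)
        for i in range(5):
            for j in range(i):
                pair = weighted_unifrac(table.iloc[i], table.iloc[j], small_tree)
                assert mat.iloc[i, j] == pytest.approx(pair, abs=1e-12)

    def test_empty_sample_raises(self, small_tree):
        taxa = [t.name for t in small_tree.tips()]
        with pytest.raises(ValueError, match="empty"):
            weighted_unifrac(np.zeros(len(taxa)), np.ones(len(taxa)),
                             small_tree, taxa=taxa)


class TestPermanova:
    def test_pseudo_f_matches_skbio(self, rng):
        pts = rng.normal(size=(24, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        mine = permanova(pd.DataFrame(d), labels, n_permutations=99, seed=0)
        ref = skbio_permanova(DistanceMatrix(d), grouping=labels, permutations=99)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)
        assert 0.0 <= mine.r_squared <= 1.0
        assert mine.p_value >= 1.0 / 100

    def test_separated_clouds_hit_p_floor(self, rng):
        a = rng.normal(size=(10, 2))
        b = rng.normal(size=(10, 2)) + 100.0
        pts = np.vstack([a, b])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = permanova(pd.DataFrame(d), ["a"] * 10 + ["b"] * 10,
                        n_permutations=999, seed=1)
        assert res.p_value == pytest.approx(1.0 / 1000)

    def test_duplicated_clouds_have_zero_r_squared(self, rng):
        pts = rng.normal(size=(5, 2))
        both = np.vstack([pts, pts])
        d = np.sqrt(((both[:, None] - both[None]) ** 2).sum(-1))
        res = permanova(pd.DataFrame(d), ["a"] * 5 + ["b"] * 5,
                        n_permutations=99, seed=2)
        assert abs(res.r_squared) < 1e-10

    def test_degenerate_grouping_rejected(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "a", "a"], seed=0)
        with pytest.raises(ValueError, match="2 members"):
            permanova(d, ["a", "a", "a", "b"], seed=0)


class TestPairwiseGroupTests:
    def test_u_statistic_identity_and_power(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100) + 1.0  # 1 SD shift
        values = np.concatenate([x, y])
        groups = ["a"] * 100 + ["b"] * 100
        res = pairwise_group_tests(values, groups)
        assert len(res) == 1
        # U + U' = n1*n2
        from scipy.stats import mannwhitneyu
        u_rev = mannwhitneyu(y, x, alternative="two-sided").statistic
        assert res.loc[0, "statistic"] + u_rev == pytest.approx(100 * 100)
        assert res.loc[0, "p_value"] < 0.05

    def test_no_shift_large_p(self):
        values = np.tile(np.arange(10.0), 2)
        groups = ["a"] * 10 + ["b"] * 10
        res = pairwise_group_tests(values, groups)
        assert res.loc[0, "p_value"] > 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_group_tests([1.0, 2.0], ["a", "a"])
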