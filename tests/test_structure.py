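"""Sample-structure diagnostics: PCA, distances, NJ trees, CV,
distance-homogeneity test and beta states."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
import skbio

from crossreg.errors import ValidationError
from crossreg.structure import (
    DistanceMatrix,
    beta_state,
    compare_group_distances,
    distance_matrix,
    nj_tree,
    pc_covariate_association,
    pca,
    sample_cv,
)


class TestPca:
    def test_two_clusters_separate_on_pc1(self, rng):
        base = rng.normal(size=50)
        cols = {}
        for i in range(3):
            cols[f"a{i}"] = base
        for i in range(3):
            cols[f"b{i}"] = base + 5
        emb = pca(pd.DataFrame(cols))
        signs = np.sign(emb.scores["PC1"])
        assert len(set(signs[:3])) == 1 and len(set(signs[3:])) == 1
        assert signs.iloc[0] != signs.iloc[-1]
        assert emb.variance_explained[0] > 0.999

    def test_duplicate_samples_share_scores(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        m["dup"] = m["a"]
        emb = pca(m)
        assert np.allclose(emb.scores.loc["a"], emb.scores.loc["dup"])

    def test_reconstruction_identity(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 6)))
        emb = pca(m)
        centered = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        rebuilt = emb.loadings.to_numpy() @ emb.scores.to_numpy().T
        assert np.allclose(rebuilt, centered, atol=1e-8)

    def test_feature_order_invariance(self, rng):
        m = pd.DataFrame(rng.normal(size=(25, 5)))
        perm = m.sample(frac=1, random_state=0)
        a, b = pca(m), pca(perm)
        assert np.allclose(np.abs(a.scores), np.abs(b.scores), atol=1e-8)

    def test_variance_explained_nonincreasing(self, rng):
        emb = pca(pd.DataFrame(rng.normal(size=(40, 8))))
        assert (np.diff(emb.variance_explained) <= 1e-12).all()
        assert emb.variance_explained.sum() <= 1 + 1e-9

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValidationError):
            pca(pd.DataFrame(rng.normal(size=(10, 1))))


class TestPcAssociation:
    def test_no_signal_gives_p_one(self):
        scores = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        factor = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        assert pc_covariate_association(scores, factor) == pytest.approx(1.0)

    def test_separated_levels_small_p(self):
        scores = pd.Series([-1.1, -0.9, -1.0, 0.9, 1.1, 1.0],
                           index=list("abcdef"))
        factor = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        p = pc_covariate_association(scores, factor)
        assert p < 1e-4
        # closed-form check via explicit least-squares F statistic
        g1, g2 = scores[:3], scores[3:]
        ssb = 3 * (g1.mean() - scores.mean()) ** 2 + 3 * (g2.mean() - scores.mean()) ** 2
        ssw = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        f = ssb / 1 / (ssw / 4)
        from scipy import stats
        assert p == pytest.approx(stats.f.sf(f, 1, 4))

    def test_permuted_labels_lose_association(self, rng):
        scores = pd.Series(np.r_[rng.normal(-1, 0.1, 5), rng.normal(1, 0.1, 5)],
                           index=[f"s{i}" for i in range(10)])
        ps = []
        for _ in range(100):
            labels = rng.permutation(["x"] * 5 + ["y"] * 5)
            ps.append(pc_covariate_association(
                scores, pd.Series(labels, index=scores.index)))
        assert np.median(ps) > 0.2

    def test_tiny_levels_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        factor = pd.Series(["x", "x", "y"], index=list("abc"))
        with pytest.raises(ValidationError):
            pc_covariate_association(scores, factor)


class TestDistances:
    def test_arithmetic(self):
        m = pd.DataFrame({"a": [0, 0], "b": [3, 4]})
        assert distance_matrix(m, "manhattan").matrix[0, 1] == 7
        assert distance_matrix(m, "euclidean").matrix[0, 1] == 5

    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=10)
        m = pd.DataFrame({"a": x, "b": x})
        assert distance_matrix(m).matrix[0, 1] == 0

    def test_symmetry_and_diagonal(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 5)))
        d = distance_matrix(m).matrix
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    def test_nan_rejected(self):
        m = pd.DataFrame({"a": [np.nan], "b": [1.0]})
        with pytest.raises(ValidationError):
            distance_matrix(m)


def random_additive_tree(rng, n_taxa=5):
    """Random binary tree with uniform branch lengths, returned as a
    newick string over taxa t0..t{n-1}."""
    nodes = [f"t{i}" for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.5, 2.0, 2)
        nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return nodes[0] + ";"


def tree_distances(newick):
    t = skbio.TreeNode.read([newick])
    dm = t.tip_tip_distances()
    labels = list(dm.ids)
    return labels, dm.data


class TestNjTree:
    def test_four_taxon_topology_recovered(self):
        labels, mat = tree_distances("((A:1,B:2):3,(C:4,D:5):1);")
        nwk = nj_tree(DistanceMatrix(labels, mat, "manhattan"))
        got = skbio.TreeNode.read([nwk])
        want = skbio.TreeNode.read(["((A:1,B:2):3,(C:4,D:5):1);"])
        assert got.compare_rfd(want) == 0

    def test_three_taxon_closed_form(self):
        mat = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        nwk = nj_tree(DistanceMatrix(list("XYZ"), mat, "manhattan"))
        assert nwk == "(X:0.5,Y:1.5,Z:2.5);"

    def test_two_clean_clusters_are_sisters(self):
        labels = ["a1", "a2", "b1", "b2", "out"]
        mat = np.full((5, 5), 10.0)
        np.fill_diagonal(mat, 0.0)
        mat[0, 1] = mat[1, 0] = 1.0
        mat[2, 3] = mat[3, 2] = 1.0
        nwk = nj_tree(DistanceMatrix(labels, mat, "manhattan"))
        tree = skbio.TreeNode.read([nwk])
        want = skbio.TreeNode.read(["((a1:1,a2:1):1,(b1:1,b2:1):1,out:1);"])
        assert tree.compare_rfd(want) == 0

    def test_random_additive_trees_recovered(self, rng):
        for _ in range(20):
            nwk_true = random_additive_tree(rng)
            labels, mat = tree_distances(nwk_true)
            got = skbio.TreeNode.read([nj_tree(DistanceMatrix(labels, mat, "manhattan"))])
            want = skbio.TreeNode.read([nwk_true])
            assert got.compare_rfd(want) == 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2)), "manhattan"))


class TestSampleCv:
    def test_constant_vector(self):
        assert sample_cv([3.0, 3.0, 3.0]) == 0

    def test_arithmetic(self):
        assert sample_cv([0.2, 0.8]) == pytest.approx(0.848528137)

    def test_scale_invariance(self, rng):
        x = rng.uniform(0.1, 1.0, 50)
        assert sample_cv(x) == pytest.approx(sample_cv(10 * x))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValidationError):
            sample_cv([0.0, 0.0])


class TestCompareGroupDistances:
    def make_dm(self, within_a, within_b):
        """Distance matrix whose within-group distances are as given."""
        labels = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        mat = np.full((8, 8), 100.0)
        np.fill_diagonal(mat, 0.0)
        pairs_a = list(itertools.combinations(range(4), 2))
        pairs_b = list(itertools.combinations(range(4, 8), 2))
        for (i, j), v in zip(pairs_a, within_a):
            mat[i, j] = mat[j, i] = v
        for (i, j), v in zip(pairs_b, within_b):
            mat[i, j] = mat[j, i] = v
        return DistanceMatrix(labels, mat, "manhattan"), labels[:4], labels[4:]

    def test_identical_multisets_p_one(self):
        vals = [1, 2, 3, 4, 5, 6]
        dm, a, b = self.make_dm(vals, vals)
        _, p = compare_group_distances(dm, a, b)
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        dm, a, b = self.make_dm([1] * 6, [10] * 6)
        u, p = compare_group_distances(dm, a, b)
        # exactly 2 of C(12,6) group assignments are this extreme
        assert p == pytest.approx(2 / comb(12, 6))

    def test_label_swap_symmetry(self, rng):
        dm, a, b = self.make_dm(rng.uniform(1, 5, 6), rng.uniform(1, 5, 6))
        _, p1 = compare_group_distances(dm, a, b)
        _, p2 = compare_group_distances(dm, b, a)
        assert p1 == pytest.approx(p2)

    def test_overlapping_groups_rejected(self):
        dm, a, b = self.make_dm([1] * 6, [2] * 6)
        with pytest.raises(ValidationError):
            compare_group_distances(dm, a, a)


class TestBetaState:
    @pytest.mark.parametrize(
        "beta, state",
        [
            (0.9, "hyper"),
            (0.8, "hyper"),
            (0.5, "hemi"),
            (0.2, "hypo"),
            (0.799999, "hemi"),
            (0.200001, "hemi"),
            (0.0, "hypo"),
            (1.0, "hyper"),
        ],
    )
    def test_states(self, beta, state):
        assert beta_state(beta) == state

    def test_vectorised(self):
        out = beta_state([0.1, 0.5, 0.95])
        assert list(out) == ["hypo", "hemi", "hyper"]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            beta_state(1.2)
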