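"""Distances, ordination and permutational tests, cross-checked against
scikit-bio as an independent oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
import skbio

from beegut import community_ecology as ce


def _table(rows, index=None, columns=None):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        rows,
        index=index or [f"s{i}" for i in range(rows.shape[0])],
        columns=columns or [f"a{i}" for i in range(rows.shape[1])],
    )


STAR_TREE = "(l1:1,l2:1,l3:1);"


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = _table([[1, 2, 3], [1, 2, 3]])
        assert ce.bray_curtis(t).data[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        t = _table([[5, 0], [0, 3]])
        assert ce.bray_curtis(t).data[0, 1] == pytest.approx(1.0)

    def test_worked_example(self):
        t = _table([[2, 2, 0], [0, 2, 2]])
        assert ce.bray_curtis(t).data[0, 1] == pytest.approx(0.5)

    def test_matches_skbio(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(0, 100, (6, 8)))
        ours = ce.bray_curtis(t).data
        ref = skbio.diversity.beta_diversity("braycurtis", t.to_numpy(),
                                             ids=list(t.index)).data
        assert np.allclose(ours, ref)


class TestUnweightedUnifrac:
    def test_identical_presence_zero(self):
        t = _table([[1, 1, 0], [2, 5, 0]], columns=["l1", "l2", "l3"])
        d = ce.unweighted_unifrac(t, STAR_TREE)
        assert d.data[0, 1] == 0.0

    def test_star_tree_hand_computation(self):
        # A = {l1, l2}, B = {l2, l3}: unique l1 + l3 = 2, union = 3
        t = _table([[1, 1, 0], [0, 1, 1]], columns=["l1", "l2", "l3"])
        d = ce.unweighted_unifrac(t, STAR_TREE)
        assert d.data[0, 1] == pytest.approx(2 / 3)

    def test_disjoint_leaves_one(self):
        t = _table([[1, 0, 0], [0, 0, 1]], columns=["l1", "l2", "l3"])
        d = ce.unweighted_unifrac(t, STAR_TREE)
        assert d.data[0, 1] == pytest.approx(1.0)

    def test_missing_leaf_raises(self):
        t = _table([[1, 1]], columns=["l1", "nope"])
        with pytest.raises(ValueError, match="nope"):
            ce.unweighted_unifrac(t, STAR_TREE)

    def test_matches_skbio_on_random_tree(self, default_dataset):
        rng = np.random.default_rng(1)
        ds = default_dataset
        asvs = list(ds.asv_counts.columns)
        t = _table(rng.integers(0, 30, (5, len(asvs))), columns=asvs)
        ours = ce.unweighted_unifrac(t, ds.tree_newick).data
        tree = skbio.TreeNode.read([ds.tree_newick])
        ref = skbio.diversity.beta_diversity(
            "unweighted_unifrac", t.to_numpy().astype(int), ids=list(t.index),
            taxa=asvs, tree=tree, validate=True,
        ).data
        assert np.allclose(ours, ref, atol=1e-10)


class TestWeightedUnifrac:
    def test_identical_compositions_zero(self):
        t = _table([[2, 4], [1, 2]], columns=["l1", "l2"])
        d = ce.weighted_unifrac(t, "(l1:1,l2:1);")
        assert d.data[0, 1] == pytest.approx(0.0)

    def test_two_leaf_closed_form(self):
        t = _table([[3, 0], [0, 7]], columns=["l1", "l2"])
        d = ce.weighted_unifrac(t, "(l1:1,l2:1);", normalized=True)
        assert d.data[0, 1] == pytest.approx(1.0)

    def test_scale_invariance(self):
        t = _table([[3, 1, 2], [1, 5, 1]], columns=["l1", "l2", "l3"])
        a = ce.weighted_unifrac(t, STAR_TREE).data[0, 1]
        t2 = t.copy()
        t2.iloc[0] *= 13.0
        b = ce.weighted_unifrac(t2, STAR_TREE).data[0, 1]
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("normalized", [True, False])
    def test_matches_skbio(self, default_dataset, normalized):
        rng = np.random.default_rng(2)
        ds = default_dataset
        asvs = list(ds.asv_counts.columns)
        t = _table(rng.integers(1, 30, (5, len(asvs))), columns=asvs)
        ours = ce.weighted_unifrac(t, ds.tree_newick, normalized=normalized).data
        tree = skbio.TreeNode.read([ds.tree_newick])
        ref = skbio.diversity.beta_diversity(
            "weighted_unifrac", t.to_numpy().astype(int), ids=list(t.index),
            taxa=asvs, tree=tree, normalized=normalized,
        ).data
        assert np.allclose(ours, ref, atol=1e-10)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([0.0, 3.0, 4.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = ce.pcoa(ce.DistanceMatrix(d, list("abc")))
        big = res.eigenvalues[np.abs(res.eigenvalues) > 1e-9]
        assert big.size == 1 and big[0] > 0
        coords = res.coordinates.to_numpy()
        emb = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        assert np.allclose(emb, d, atol=1e-9)

    def test_regular_simplex_equal_eigenvalues(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        res = ce.pcoa(ce.DistanceMatrix(d, [f"s{i}" for i in range(n)]))
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert pos.size == n - 1
        assert np.allclose(pos, pos[0])

    def test_euclidean_input_no_negative_eigenvalues(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        res = ce.pcoa(ce.DistanceMatrix(d, [f"s{i}" for i in range(8)]))
        assert res.eigenvalues.min() > -1e-9

    def test_matches_skbio_proportions(self):
        rng = np.random.default_rng(4)
        t = _table(rng.integers(0, 60, (7, 5)))
        dm = ce.bray_curtis(t)
        ours = ce.pcoa(dm)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.data, ids=dm.ids)
        )
        n_ax = ours.coordinates.shape[1]
        assert np.allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(ref.samples.to_numpy()[:, :n_ax]),
            atol=1e-8,
        )


class TestPermanova:
    def _two_clouds(self, sep, n=10, seed=5):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n, 3))
        b = rng.normal(sep, 1, (n, 3))
        x = np.vstack([a, b])
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        ids = [f"s{i}" for i in range(2 * n)]
        return ce.DistanceMatrix(d, ids), ["A"] * n + ["B"] * n

    def test_separated_clouds_significant(self):
        dm, grouping = self._two_clouds(5.0)
        res = ce.permanova(dm, grouping, n_permutations=999, seed=1)
        assert res.effect_size > 0.5
        assert res.p_value <= 0.001

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (6, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        dm = ce.DistanceMatrix(d, [f"s{i}" for i in range(6)])
        grouping = ["A", "A", "A", "B", "B", "B"]
        res = ce.permanova(dm, grouping, permutations="exhaustive")
        # brute force: F for all 20 distinct splits, p = fraction >= observed
        d2 = d**2

        def f_of(codes):
            codes = np.asarray(codes)
            n = 6
            sst = d2[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for g in (0, 1):
                idx = np.where(codes == g)[0]
                ssw += d2[np.ix_(idx, idx)][np.triu_indices(3, 1)].sum() / 3
            ssb = sst - ssw
            return (ssb / 1) / (ssw / 4)

        obs = f_of([0, 0, 0, 1, 1, 1])
        fs = [
            f_of([0 if i in comb else 1 for i in range(6)])
            for comb in itertools.combinations(range(6), 3)
        ]
        p_brute = np.mean([f >= obs for f in fs])
        assert res.p_value == pytest.approx(p_brute)
        assert res.statistic == pytest.approx(obs)

    def test_matches_skbio_statistic(self):
        dm, grouping = self._two_clouds(1.0, n=8, seed=7)
        ours = ce.permanova(dm, grouping, n_permutations=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, ids=dm.ids), grouping, permutations=0
        )
        assert ours.statistic == pytest.approx(ref["test statistic"])

    def test_all_identical_points_degenerate(self):
        d = np.zeros((6, 6))
        dm = ce.DistanceMatrix(d, [f"s{i}" for i in range(6)])
        res = ce.permanova(dm, ["A"] * 3 + ["B"] * 3, n_permutations=99, seed=0)
        assert res.p_value == 1.0

    def test_singleton_group_rejected(self):
        dm, _ = self._two_clouds(1.0, n=3)
        with pytest.raises(ValueError):
            ce.permanova(dm, ["A"] * 5 + ["B"], n_permutations=99)

    def test_euclidean_1d_equals_classic_anova_f(self):
        from beegut import stats_core

        vals = np.array([1.0, 2.0, 1.5, 5.0, 6.0, 5.5, 9.0, 8.5, 9.5])
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        d = np.abs(vals[:, None] - vals[None, :])
        dm = ce.DistanceMatrix(d, [f"s{i}" for i in range(9)])
        res = ce.permanova(dm, groups, n_permutations=99, seed=0)
        ref = stats_core.anova_oneway(vals, groups)
        assert res.statistic == pytest.approx(ref.statistic)


class TestAnosim:
    def test_complete_separation_r_one(self):
        d = np.array(
            [
                [0, 1, 1, 9, 9],
                [1, 0, 1, 9, 9],
                [1, 1, 0, 9, 9],
                [9, 9, 9, 0, 1],
                [9, 9, 9, 1, 0],
            ],
            dtype=float,
        )
        dm = ce.DistanceMatrix(d, list("abcde"))
        res = ce.anosim(dm, ["A", "A", "A", "B", "B"], n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(8)
        rs = []
        for _ in range(60):
            x = rng.normal(size=(8, 2))
            d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
            dm = ce.DistanceMatrix(d, [f"s{i}" for i in range(8)])
            res = ce.anosim(dm, ["A"] * 4 + ["B"] * 4, n_permutations=99, seed=0)
            rs.append(res.statistic)
        assert abs(np.mean(rs)) < 0.1

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(10, 3))
        x[5:] += 1.0
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        dm = ce.DistanceMatrix(d, [f"s{i}" for i in range(10)])
        grouping = ["A"] * 5 + ["B"] * 5
        ours = ce.anosim(dm, grouping, n_permutations=99, seed=0)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d, ids=dm.ids), grouping, permutations=0
        )
        assert ours.statistic == pytest.approx(ref["test statistic"])

    def test_exhaustive_close_to_sampled(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(6, 2))
        x[3:] += 1.5
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        dm = ce.DistanceMatrix(d, [f"s{i}" for i in range(6)])
        grouping = ["A"] * 3 + ["B"] * 3
        exact = ce.anosim(dm, grouping, permutations="exhaustive")
        sampled = ce.anosim(dm, grouping, n_permutations=4999, seed=1)
        # 3 Monte-Carlo standard errors
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 4999)
        assert abs(exact.p_value - sampled.p_value) <= 3 * se + 1e-4


class TestPermdisp:
    def test_mirror_groups_null(self):
        # two groups with the same dispersion pattern
        x = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        d = np.abs(x - x.T)
        dm = ce.DistanceMatrix(d, [f"s{i}" for i in range(6)])
        res = ce.permdisp(dm, ["A"] * 3 + ["B"] * 3, n_permutations=199, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.5

    def test_inflated_cluster_detected(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, (10, 2))
        b = rng.normal(0, 5, (10, 2))
        x = np.vstack([a, b])
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        dm = ce.DistanceMatrix(d, [f"s{i}" for i in range(20)])
        res = ce.permdisp(dm, ["A"] * 10 + ["B"] * 10, n_permutations=999, seed=0)
        assert res.p_value <= 0.01

    def test_matches_skbio_statistic_euclidean(self):
        # with a Euclidean matrix (no negative eigenvalues) every
        # implementation agrees; checks the embedding + F machinery
        rng = np.random.default_rng(12)
        x = rng.normal(size=(12, 4))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        dm = ce.DistanceMatrix(d, [f"s{i}" for i in range(12)])
        grouping = ["A"] * 6 + ["B"] * 6
        ours = ce.permdisp(dm, grouping, n_permutations=99, seed=0)
        ref = skbio.stats.distance.permdisp(
            skbio.DistanceMatrix(d, ids=dm.ids), grouping, permutations=0,
            test="centroid", dimensions=11,
        )
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_matches_vegan_betadisper_non_euclidean(self, tmp_path):
        # Bray-Curtis is non-Euclidean: the negative-eigenvalue correction
        # must match the reference betadisper (centroid) implementation
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(12)
        t = _table(rng.integers(1, 80, (12, 6)))
        dm = ce.bray_curtis(t)
        grouping = ["A"] * 6 + ["B"] * 6
        ours = ce.permdisp(dm, grouping, n_permutations=99, seed=0)
        csv = tmp_path / "dm.csv"
        dm.to_frame().to_csv(csv)
        script = (
            'suppressMessages(library(vegan));'
            f'm <- as.matrix(read.csv("{csv}", row.names=1));'
            'b <- betadisper(as.dist(m), factor(rep(c("A","B"), each=6)),'
            ' type="centroid");'
            'cat(anova(b)$`F value`[1], "\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ref_f = float(out.stdout.strip().split()[-1])
        assert ours.statistic == pytest.approx(ref_f, rel=1e-5)


class TestDistanceInvariants:
    @pytest.mark.parametrize("metric", ["bray", "uw", "w"])
    def test_symmetry_zero_diagonal_reorder(self, metric, default_dataset):
        rng = np.random.default_rng(13)
        ds = default_dataset
        asvs = list(ds.asv_counts.columns)
        t = _table(rng.integers(1, 40, (6, len(asvs))), columns=asvs)
        fn = {
            "bray": lambda x: ce.bray_curtis(x),
            "uw": lambda x: ce.unweighted_unifrac(x, ds.tree_newick),
            "w": lambda x: ce.weighted_unifrac(x, ds.tree_newick),
        }[metric]
        d = fn(t)
        assert np.allclose(d.data, d.data.T)
        assert np.allclose(np.diag(d.data), 0)
        perm = [3, 1, 5, 0, 2, 4]
        d2 = fn(t.iloc[perm])
        assert np.allclose(d2.data, d.data[np.ix_(perm, perm)])
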