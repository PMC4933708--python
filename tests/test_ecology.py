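"""Normalization, rarefaction, Bray-Curtis, PCoA, UPGMA and PERMANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from microbialite import ecology as eco
from microbialite.ecology import CountTable


def _table(arr, groups=None):
    arr = np.asarray(arr)
    cols = [f"s{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])], columns=cols)
    if groups is None:
        groups = {c: "g" for c in cols}
    return CountTable(df, groups)


class TestNormalizeDepth:
    def test_double_depth_halves(self):
        t = _table([[4], [6]])  # total 10
        out = eco.normalize_depth(t, 5)
        assert out.counts["s0"].tolist() == [2.0, 3.0]

    def test_identity_at_depth(self):
        t = _table([[4], [6]])
        out = eco.normalize_depth(t, 10)
        assert np.allclose(out.counts.to_numpy(), t.counts.to_numpy())

    def test_column_sums_equal_depth(self, rng):
        t = _table(rng.integers(0, 100, (30, 6)) + 1)
        out = eco.normalize_depth(t, 221_168)
        assert np.allclose(out.counts.sum(axis=0), 221_168, atol=1e-9)

    def test_zero_total_sample_named(self):
        t = _table([[0, 1], [0, 2]])
        with pytest.raises(ValueError, match="s0"):
            eco.normalize_depth(t, 10)

    def test_rarefy_counts_seeded_and_at_depth(self, rng):
        t = _table(rng.integers(0, 50, (20, 4)) + 1)
        a = eco.rarefy_counts(t, 100, seed=3)
        b = eco.rarefy_counts(t, 100, seed=3)
        assert a.counts.equals(b.counts)
        assert (a.counts.sum(axis=0) == 100).all()


class TestRelativeAbundance:
    def test_single_feature_proportion_one(self):
        t = _table([[7, 3]])
        props = eco.relative_abundance(t)
        assert np.allclose(props.to_numpy(), 1.0)

    def test_filter_strictly_greater(self):
        props = pd.DataFrame({"s0": [0.005, 0.0051, 0.99]}, index=["a", "b", "c"])
        kept = eco.abundance_filter(props, min_frac=0.005)
        assert list(kept.index) == ["b", "c"]

    def test_toy_proportions_match_hand_arithmetic(self):
        t = _table([[1, 2], [3, 2], [6, 6]])
        props = eco.relative_abundance(t)
        assert props["s0"].tolist() == [0.1, 0.3, 0.6]
        assert props["s1"].tolist() == [0.2, 0.2, 0.6]


class TestRarefaction:
    def test_full_depth_equals_observed_richness(self):
        t = _table([[5], [3], [0], [2]])
        curve = eco.rarefaction_curve(t, [10])
        assert curve.expected_richness["s0"].iloc[0] == pytest.approx(3.0)

    def test_single_read_observes_one_feature(self):
        t = _table([[5], [3]])
        curve = eco.rarefaction_curve(t, [1])
        assert curve.expected_richness["s0"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_two_even_features(self):
        # counts (5, 5), n=2: E = 2*(1 - C(5,2)/C(10,2)) = 14/9
        t = _table([[5], [5]])
        curve = eco.rarefaction_curve(t, [2])
        assert curve.expected_richness["s0"].iloc[0] == pytest.approx(14.0 / 9.0)

    def test_monotone_in_depth(self, rng):
        t = _table(rng.integers(0, 40, (25, 1)) + 0)
        total = int(t.counts["s0"].sum())
        curve = eco.rarefaction_curve(t, range(1, total + 1, max(total // 17, 1)))
        vals = curve.expected_richness["s0"].to_numpy()
        assert (np.diff(vals) >= -1e-12).all()

    def test_matches_monte_carlo(self, rng):
        counts = np.array([12, 7, 3, 1, 0, 25])
        t = _table(counts.reshape(-1, 1))
        depth = 10
        expected = eco.rarefaction_curve(t, [depth]).expected_richness["s0"].iloc[0]
        pool = np.repeat(np.arange(len(counts)), counts)
        draws = np.array(
            [
                len(np.unique(rng.choice(pool, size=depth, replace=False)))
                for _ in range(10_000)
            ]
        )
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    def test_depth_beyond_total_rejected(self):
        t = _table([[2], [3]])
        with pytest.raises(ValueError, match="exceeds"):
            eco.rarefaction_curve(t, [6])


class TestBrayCurtis:
    def test_identical_zero_and_disjoint_one(self):
        t = _table([[1, 1, 0], [2, 2, 0], [0, 0, 5]])
        d = eco.bray_curtis_matrix(t)
        assert d.loc["s0", "s1"] == pytest.approx(0.0)
        assert d.loc["s0", "s2"] == pytest.approx(1.0)

    def test_hand_value(self):
        t = _table([[1, 3], [2, 0]])
        d = eco.bray_curtis_matrix(t)
        assert d.loc["s0", "s1"] == pytest.approx(4.0 / 6.0)

    @given(
        arrays(
            np.float64,
            (4, 3),
            elements=st.floats(0.0, 100.0),
        ).filter(lambda a: (a.sum(axis=0) > 0).all())
    )
    @settings(max_examples=100, deadline=None)
    def test_metric_properties(self, arr):
        d = eco.bray_curtis_matrix(_table(arr)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()

    def test_feature_permutation_invariance(self, rng):
        arr = rng.integers(1, 50, (12, 4))
        d1 = eco.bray_curtis_matrix(_table(arr)).to_numpy()
        d2 = eco.bray_curtis_matrix(_table(arr[rng.permutation(12)])).to_numpy()
        assert np.allclose(d1, d2)


def _dist(mat, ids=None):
    mat = np.asarray(mat, dtype=float)
    ids = ids or [f"s{i}" for i in range(mat.shape[0])]
    return pd.DataFrame(mat, index=ids, columns=ids)


class TestPcoa:
    def test_two_samples(self):
        res = eco.pcoa(_dist([[0, 4], [4, 0]]))
        coords = res.coordinates["PC1"].to_numpy()
        assert sorted(np.abs(coords)) == pytest.approx([2.0, 2.0])
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_round_trip(self, rng):
        pts = rng.normal(size=(4, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = eco.pcoa(_dist(d))
        rec = res.coordinates.to_numpy()
        d_rec = np.linalg.norm(rec[:, None] - rec[None, :], axis=2)
        assert np.allclose(d_rec, d, atol=1e-8)

    def test_collinear_points_have_one_axis(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        res = eco.pcoa(_dist(d))
        assert res.coordinates.shape[1] == 1

    def test_eigenvalues_descending(self, rng):
        arr = rng.integers(1, 50, (20, 6))
        d = eco.bray_curtis_matrix(_table(arr))
        res = eco.pcoa(d)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_agrees_with_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(6, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ours = eco.pcoa(_dist(d))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        n = ours.coordinates.shape[1]
        for k in range(n):
            a = ours.coordinates.iloc[:, k].to_numpy()
            b = ref.samples.iloc[:, k].to_numpy()
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)


class TestUpgma:
    def test_two_leaves(self):
        tree = eco.upgma(_dist([[0, 3], [3, 0]], ["A", "B"]))
        assert tree.height == pytest.approx(1.5)
        assert sorted(tree.leaves()) == ["A", "B"]

    def test_three_leaf_hand_case(self):
        d = _dist([[0, 2, 8], [2, 0, 8], [8, 8, 0]], ["A", "B", "C"])
        tree = eco.upgma(d)
        assert tree.height == pytest.approx(4.0)
        inner = [c for c in tree.children if c.children]
        assert len(inner) == 1
        assert inner[0].height == pytest.approx(1.0)
        assert sorted(inner[0].leaves()) == ["A", "B"]

    def test_ultrametric_heights(self, rng):
        arr = rng.integers(1, 60, (15, 6))
        d = eco.bray_curtis_matrix(_table(arr))
        tree = eco.upgma(d)

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(tree)

    def test_matches_average_linkage_cophenetic(self, rng):
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        arr = rng.integers(1, 60, (15, 6))
        d = eco.bray_curtis_matrix(_table(arr))
        tree = eco.upgma(d)

        # cophenetic distance on our tree = 2 * height of the LCA
        leaves = d.index.tolist()
        coph_ours = {}

        def collect(node):
            if not node.children:
                return [node.name]
            sides = [collect(c) for c in node.children]
            for a_side, b_side in itertools.combinations(sides, 2):
                for a in a_side:
                    for b in b_side:
                        coph_ours[frozenset((a, b))] = 2 * node.height
            return [x for side in sides for x in side]

        collect(tree)
        z = average(squareform(d.to_numpy()))
        coph_ref = squareform(cophenet(z))
        for i, a in enumerate(leaves):
            for j in range(i + 1, len(leaves)):
                assert coph_ours[frozenset((a, leaves[j]))] == pytest.approx(
                    coph_ref[i, j]
                )

    def test_newick_round_trip(self):
        d = _dist([[0, 2, 8], [2, 0, 8], [8, 8, 0]], ["A", "B", "C"])
        nwk = eco.tree_to_newick(eco.upgma(d))
        assert nwk.endswith(";")
        skbio = pytest.importorskip("skbio")
        t = skbio.TreeNode.read([nwk])
        assert sorted(x.name for x in t.tips()) == ["A", "B", "C"]
        assert t.find("A").accumulate_to_ancestor(t) == pytest.approx(4.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            eco.upgma(_dist([[0.0]]))


class TestPermanova:
    def _toy(self, rng, n=4):
        pts = rng.normal(size=(n, 3))
        pts[: n // 2] += 2.0
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
        return _dist(d), labels

    def test_degenerate_all_identical(self):
        res = eco.permanova(_dist(np.zeros((4, 4))), ["a", "a", "b", "b"], seed=0)
        assert res.p_value == 1.0
        assert res.r_squared == 0.0

    def test_exact_enumeration_matches_independent_oracle(self, rng):
        d, labels = self._toy(rng)
        res = eco.permanova(d, labels, exact=True)

        # independent oracle: enumerate label orderings, compute pseudo-F
        # from scratch via group sums of squared distances
        def brute_f(a, lab):
            a2 = a**2
            n = len(lab)
            sst = a2[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for gname in set(lab):
                idx = [i for i, x in enumerate(lab) if x == gname]
                block = sum(a2[i, j] for ii, i in enumerate(idx) for j in idx[ii + 1 :])
                ssw += block / len(idx)
            ssa = sst - ssw
            return (ssa / 1) / (ssw / (n - 2))

        a = d.to_numpy()
        f_obs = brute_f(a, labels)
        perms = set(itertools.permutations(labels))
        count = sum(1 for p in perms if brute_f(a, list(p)) >= f_obs - 1e-12)
        assert res.p_value == pytest.approx(count / len(perms))
        assert res.pseudo_f == pytest.approx(f_obs)

    def test_seed_reproducibility_and_resolution(self, rng):
        d, labels = self._toy(rng, n=6)
        r1 = eco.permanova(d, labels, n_perm=99, seed=11)
        r2 = eco.permanova(d, labels, n_perm=99, seed=11)
        assert r1 == r2
        # p has resolution 1/(n_perm+1)
        assert round(r1.p_value * 100) == pytest.approx(r1.p_value * 100)

    def test_r2_in_unit_interval_and_label_permutation_consistency(self, rng):
        d, labels = self._toy(rng, n=8)
        res = eco.permanova(d, labels, n_perm=49, seed=1)
        assert 0.0 <= res.r_squared <= 1.0
        perm = rng.permutation(len(labels))
        d2 = d.iloc[perm, perm]
        labels2 = [labels[i] for i in perm]
        res2 = eco.permanova(d2, labels2, n_perm=49, seed=1)
        assert res2.r_squared == pytest.approx(res.r_squared)
        assert res2.pseudo_f == pytest.approx(res.pseudo_f)

    def test_agrees_with_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        d, labels = self._toy(rng, n=8)
        ours = eco.permanova(d, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.to_numpy(), ids=d.index), labels, permutations=99
        )
        assert ours.pseudo_f == pytest.approx(ref["test statistic"])

    def test_single_group_rejected(self, rng):
        d, _ = self._toy(rng)
        with pytest.raises(ValueError):
            eco.permanova(d, ["a"] * 4, seed=0)

    def test_null_rejection_rate_calibrated(self, rng):
        # labels carry no signal: rejection at alpha = 0.05 should be 5%
        # within 3 Monte-Carlo standard errors over 1000 replicates.  A 5+5
        # design is used because at 3+3 the permutation distribution has
        # only 10 distinct partitions (minimum attainable p = 0.1), so a
        # 5% test cannot reject at all there.
        n_rep = 1000
        labels = ["a"] * 5 + ["b"] * 5
        rejections = 0
        for _ in range(n_rep):
            pts = rng.normal(size=(10, 3))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            res = eco.permanova(
                _dist(d), labels, n_perm=199, seed=int(rng.integers(2**31))
            )
            rejections += res.p_value <= 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_rep)
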