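"""Diversity, ordination, permutation tests and clustering statistics.

Independent oracles: scipy and scikit-bio reference implementations on
small fixtures, hand-computed closed forms, and exhaustive enumeration
for small permutation nulls.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from rindvirome.ecology import (
    DistanceMatrix,
    bray_curtis,
    bray_curtis_matrix,
    cut_clusters,
    hclust_complete,
    kruskal_wallis,
    linkage_to_newick,
    mantel,
    pcoa,
    permanova,
    shannon,
    spearman_matrix,
    wss_cluster_count,
)


class TestShannon:
    def test_closed_forms(self):
        assert shannon([0.25] * 4) == pytest.approx(np.log(4))
        assert shannon([1.0]) == 0.0
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.5 * np.log(2))

    def test_base_conversion(self):
        assert shannon([0.25] * 4, base=2) == pytest.approx(2.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shannon([1.2, -0.2])


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 0], [0, 4]) == 1.0

    def test_hand_value(self):
        assert bray_curtis([6, 4], [2, 8]) == pytest.approx(8 / 20)

    def test_matrix_agrees_with_scipy(self, rng):
        from scipy.spatial.distance import braycurtis as scipy_bc

        table = pd.DataFrame(rng.random((5, 8)), index=[f"s{i}" for i in range(5)])
        d = bray_curtis_matrix(table)
        for i in range(5):
            for j in range(5):
                expect = 0.0 if i == j else scipy_bc(table.iloc[i], table.iloc[j])
                assert d.values[i, j] == pytest.approx(expect)

    def test_scale_invariance_after_tss(self, rng):
        table = pd.DataFrame(rng.random((4, 6)) + 0.1)
        rel = table.div(table.sum(axis=1), axis=0)
        scaled = rel * 7.3
        np.testing.assert_allclose(
            bray_curtis_matrix(rel).values, bray_curtis_matrix(scaled).values, atol=1e-12
        )


class TestPcoa:
    def test_euclidean_reconstruction(self):
        """A 3-4-5 right triangle embeds exactly; coordinates must reproduce
        the input distances."""
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, explained = pcoa(DistanceMatrix(["a", "b", "c"], d))
        rec = np.sqrt(((coords.to_numpy()[:, None] - coords.to_numpy()[None]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, d, atol=1e-9)
        assert explained.sum() == pytest.approx(1.0)

    def test_identical_samples_degenerate(self):
        d = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        coords, explained = pcoa(d)
        assert coords.shape[1] == 0

    def test_axes_ordered_by_variance(self, rng):
        x = rng.random((6, 4))
        diff = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        coords, explained = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], diff))
        assert np.all(np.diff(explained) <= 1e-12)

    def test_agrees_with_skbio(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix as SkbioDM

        table = pd.DataFrame(rng.random((6, 10)), index=[f"s{i}" for i in range(6)])
        d = bray_curtis_matrix(table)
        ours_coords, ours_explained = pcoa(d)
        ref = skbio_pcoa(SkbioDM(d.values, ids=d.ids), number_of_dimensions=2)
        ref_expl = ref.proportion_explained.to_numpy()[:2]
        # same explained-variance spectrum (signs/rotations of axes are free)
        assert ours_explained[:2] == pytest.approx(ref_expl, abs=1e-6)
        np.testing.assert_allclose(
            np.abs(ours_coords.to_numpy()[:, 0]),
            np.abs(ref.samples.to_numpy()[:, 0]),
            atol=1e-6,
        )


class TestPermanova:
    def _distance(self, rng, n=12, shift=0.0, noise=1.0):
        x = rng.random((n, 6)) * noise + 1.0
        x[n // 2:] += shift
        diff = np.abs(x[:, None] - x[None]).sum(-1) / (x[:, None] + x[None]).sum(-1)
        np.fill_diagonal(diff, 0)
        return DistanceMatrix([f"s{i}" for i in range(n)], diff)

    def test_strong_separation(self, rng):
        d = self._distance(rng, shift=50.0, noise=0.05)
        groups = ["a"] * 6 + ["b"] * 6
        res = permanova(d, groups, n_perm=999, seed=1)
        # a random permutation reproduces the original split w.p. 1/C(12,6),
        # so p can exceed the 1/(n_perm+1) floor by a count or two
        assert res.p <= 3 / 1000
        assert res.R2 > 0.9

    def test_statistic_matches_skbio(self, rng):
        from skbio.stats.distance import permanova as skbio_permanova
        from skbio import DistanceMatrix as SkbioDM

        d = self._distance(rng, shift=0.5)
        groups = ["a"] * 6 + ["b"] * 6
        ours = permanova(d, groups, n_perm=99, seed=0)
        ref = skbio_permanova(SkbioDM(d.values, ids=d.ids), grouping=groups, permutations=99)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_small_n_matches_exhaustive_null(self, rng):
        """n=4 (two groups of two): the permutation p-value must agree with
        exhaustive enumeration over all label orderings."""
        d = self._distance(rng, n=4, shift=1.0)
        groups = np.array(["a", "a", "b", "b"])
        res = permanova(d, groups, n_perm=999, seed=3)
        f_obs = res.pseudo_F
        f_all = []
        for perm in itertools.permutations(range(4)):
            f_all.append(permanova(d, groups[list(perm)], n_perm=1, seed=0).pseudo_F)
        exact = np.mean([f >= f_obs - 1e-12 for f in f_all])
        assert res.p == pytest.approx(exact, abs=0.1)

    def test_empty_group_rejected(self, rng):
        d = self._distance(rng, n=4)
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 4, n_perm=9, seed=0)


class TestMantel:
    def _pair(self, rng, n=10):
        x = rng.random((n, 5))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        return DistanceMatrix([f"s{i}" for i in range(n)], d)

    def test_self_correlation(self, rng):
        d = self._pair(rng)
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_rank_invariance(self, rng):
        d = self._pair(rng)
        d2 = DistanceMatrix(d.ids, d.values ** 2)  # strictly monotone transform
        assert mantel(d, d2, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_r_matches_skbio(self, rng):
        from skbio.stats.distance import mantel as skbio_mantel
        from skbio import DistanceMatrix as SkbioDM

        d1, d2 = self._pair(rng), self._pair(rng)
        ours = mantel(d1, d2, n_perm=99, seed=0)
        ref_r, _, _ = skbio_mantel(
            SkbioDM(d1.values, ids=d1.ids), SkbioDM(d2.values, ids=d2.ids),
            method="spearman", permutations=0,
        )
        assert ours.r == pytest.approx(ref_r, abs=1e-9)

    def test_too_small_rejected(self, rng):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            mantel(d, d, n_perm=9, seed=0)


class TestKruskalWallis:
    def test_hand_computed_value(self):
        """Groups (1,2,3) vs (10,11,12): ranks 1..6, H = 3.857 with no ties."""
        h, p = kruskal_wallis([np.array([1, 2, 3]), np.array([10, 11, 12])])
        assert h == pytest.approx(27 / 7, abs=1e-3)

    def test_matches_scipy_with_ties(self, rng):
        from scipy.stats import kruskal

        groups = [rng.integers(0, 5, 8).astype(float) for _ in range(3)]
        h, p = kruskal_wallis(groups)
        ref = kruskal(*groups)
        assert h == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_constant_data(self):
        h, p = kruskal_wallis([np.ones(4), np.ones(3)])
        assert (h, p) == (0.0, 1.0)


class TestSpearmanMatrix:
    def test_monotone_relationships(self):
        samples = [f"s{i}" for i in range(6)]
        x = np.arange(6, dtype=float)
        a = pd.DataFrame({"up": x, "down": -x}, index=samples)
        b = pd.DataFrame({"host": x ** 2}, index=samples)  # monotone in x
        r = spearman_matrix(a, b)
        assert r.loc["up", "host"] == pytest.approx(1.0)
        assert r.loc["down", "host"] == pytest.approx(-1.0)

    def test_zero_variance_is_nan_not_zero(self):
        samples = [f"s{i}" for i in range(5)]
        a = pd.DataFrame({"flat": np.ones(5)}, index=samples)
        b = pd.DataFrame({"x": np.arange(5.0)}, index=samples)
        assert np.isnan(spearman_matrix(a, b).loc["flat", "x"])

    def test_matches_scipy(self, rng):
        from scipy.stats import spearmanr

        samples = [f"s{i}" for i in range(8)]
        a = pd.DataFrame(rng.random((8, 3)), index=samples, columns=list("abc"))
        b = pd.DataFrame(rng.random((8, 2)), index=samples, columns=list("xy"))
        r = spearman_matrix(a, b)
        for ca in a.columns:
            for cb in b.columns:
                assert r.loc[ca, cb] == pytest.approx(spearmanr(a[ca], b[cb]).statistic)


class TestHclust:
    def test_identical_profiles_merge_first(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=["a", "b", "c"]
        )
        merges, order = hclust_complete(profiles)
        assert merges[0, 2] == 0.0  # first merge at height 0
        assert abs(order.index("a") - order.index("b")) == 1  # identical pair adjacent

    def test_hand_dendrogram_complete_linkage(self):
        """Distances 1 (a,b), ~10 (a,c), ~10 (b,c): the close pair merges at 1,
        the final complete-linkage merge at max(d(a,c), d(b,c))."""
        profiles = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        merges, _ = hclust_complete(profiles)
        assert merges[0, 2] == pytest.approx(1.0)
        assert merges[1, 2] == pytest.approx(10.0)  # max(9, 10)

    def test_heights_match_scipy(self, rng):
        from scipy.cluster.hierarchy import linkage

        profiles = pd.DataFrame(rng.random((9, 4)), index=[f"f{i}" for i in range(9)])
        merges, _ = hclust_complete(profiles)
        ref = linkage(profiles.to_numpy(), method="complete", metric="euclidean")
        np.testing.assert_allclose(np.sort(merges[:, 2]), np.sort(ref[:, 2]), atol=1e-9)

    def test_input_order_invariance(self, rng):
        profiles = pd.DataFrame(rng.random((8, 3)), index=[f"f{i}" for i in range(8)])
        _, order1 = hclust_complete(profiles)
        shuffled = profiles.sample(frac=1.0, random_state=5)
        _, order2 = hclust_complete(shuffled)
        merges1, _ = hclust_complete(profiles)
        k3_a = dict(zip(profiles.index, cut_clusters(merges1, 8, 3)))
        merges2, _ = hclust_complete(shuffled)
        k3_b = dict(zip(shuffled.index, cut_clusters(merges2, 8, 3)))
        # same partition regardless of row order
        part_a = {frozenset(i for i, g in k3_a.items() if g == lab) for lab in set(k3_a.values())}
        part_b = {frozenset(i for i, g in k3_b.items() if g == lab) for lab in set(k3_b.values())}
        assert part_a == part_b

    def test_newick_export_parses(self):
        profiles = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        merges, _ = hclust_complete(profiles)
        nwk = linkage_to_newick(merges, ["a", "b", "c"])
        assert nwk.endswith(";") and "a" in nwk and "(" in nwk


class TestWss:
    def _planted(self, rng, k=5, per=8, sep=30.0):
        # cluster centers in random directions so between-cluster distances
        # are comparable (collinear centers would bias the elbow toward k=2)
        rowsets = []
        ids = []
        for g in range(k):
            center = rng.normal(0, sep, 6)
            rowsets.append(center + rng.normal(0, 0.5, (per, 6)))
            ids += [f"g{g}_f{j}" for j in range(per)]
        return pd.DataFrame(np.vstack(rowsets), index=ids)

    def test_wss_zero_at_n_and_nonincreasing(self, rng):
        profiles = self._planted(rng, k=2, per=3)
        wss, _ = wss_cluster_count(profiles, k_max=5)
        assert np.all(np.diff(wss) <= 1e-9)
        merges, _ = hclust_complete(profiles)
        labels = cut_clusters(merges, 6, 6)
        assert len(set(labels)) == 6

    def test_elbow_finds_planted_cluster_count(self, rng):
        profiles = self._planted(rng, k=5, per=8)
        wss, chosen = wss_cluster_count(profiles, k_max=10)
        assert chosen == 5
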