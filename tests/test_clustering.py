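"""Ward trees, bootstrap support, standardisation, k-means and template
labelling — each checked against brute-force oracles where one exists."""

import numpy as np
import pandas as pd
import pytest

import hifmimic as hm
from hifmimic.clustering import (
    DistanceMatrix,
    bootstrap_support,
    kmeans_assign,
    label_clusters_by_template,
    manhattan_distances,
    standardize_rows,
    ward_agglomerate,
)


def brute_force_ward(points):
    """Direct Ward agglomeration from coordinates: at every step merge the
    pair of clusters whose union minimises the increase in total
    within-cluster sum of squares, recomputed from cluster sums. Returns the
    sequence of merged leaf-sets and the Ward.D2 heights sqrt(2 * dESS)."""
    points = np.asarray(points, dtype=float)
    clusters = [({i}, points[i].copy(), 1) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                si, ci, ni = clusters[i]
                sj, cj, nj = clusters[j]
                mi, mj = ci / ni, cj / nj
                d_ess = ni * nj / (ni + nj) * np.sum((mi - mj) ** 2)
                if best is None or d_ess < best[0] - 1e-12:
                    best = (d_ess, i, j)
        d_ess, i, j = best
        si, ci, ni = clusters[i]
        sj, cj, nj = clusters[j]
        merged = (si | sj, ci + cj, ni + nj)
        merges.append((frozenset(si | sj), np.sqrt(2 * d_ess)))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


class TestManhattan:
    def test_direct_sum(self):
        d = manhattan_distances(pd.DataFrame([[0, 0], [1, 2]], index=["a", "b"]))
        assert d.values[0, 1] == pytest.approx(3.0)

    def test_zero_self_distance(self, rng):
        x = pd.DataFrame(rng.normal(size=(6, 3)))
        d = manhattan_distances(x)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_matches_elementwise_loop(self, rng):
        x = rng.normal(size=(5, 4))
        d = manhattan_distances(pd.DataFrame(x)).values
        for i in range(5):
            for j in range(5):
                assert d[i, j] == pytest.approx(sum(abs(x[i] - x[j])))

    def test_columns_axis(self, rng):
        x = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        d = manhattan_distances(x, axis="columns")
        assert d.ids == ("a", "b", "c")

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            manhattan_distances(pd.DataFrame([[0.0, np.nan]]))


class TestWard:
    def test_three_point_line_first_merge(self):
        d = manhattan_distances(pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc")))
        dend = ward_agglomerate(d)
        assert set(dend.merges[0, :2]) == {0, 1}

    def test_structural_contract(self, rng):
        x = pd.DataFrame(rng.normal(size=(9, 4)))
        dend = ward_agglomerate(manhattan_distances(x))
        assert dend.merges.shape == (8, 4)
        heights = dend.merges[:, 2]
        assert (np.diff(heights) >= -1e-9).all()

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_matches_brute_force_on_euclidean_instances(self, n, rng):
        """On Euclidean distances, Ward.D2 equals direct ESS-minimising
        agglomeration; compare merge-for-merge on random instances."""
        for trial in range(20):
            pts = rng.normal(size=(n, 3))
            from scipy.spatial.distance import pdist, squareform
            d = DistanceMatrix(
                tuple(str(i) for i in range(n)), squareform(pdist(pts))
            )
            dend = ward_agglomerate(d)
            oracle = brute_force_ward(pts)
            got = [
                (frozenset(int(m) for m in sorted(leafset, key=int)), h)
                for leafset, h in zip(
                    ({int(x) for x in s} for s in dend.node_leafsets()),
                    dend.merges[:, 2],
                )
            ]
            for (leaves_a, h_a), (leaves_b, h_b) in zip(got, oracle):
                assert {int(x) for x in leaves_a} == {int(x) for x in leaves_b}
                assert h_a == pytest.approx(h_b)

    def test_permutation_invariance_up_to_relabel(self, rng):
        x = rng.normal(size=(7, 3))
        d1 = manhattan_distances(pd.DataFrame(x, index=[f"i{k}" for k in range(7)]))
        perm = rng.permutation(7)
        d2 = manhattan_distances(
            pd.DataFrame(x[perm], index=[f"i{k}" for k in perm])
        )
        s1 = {frozenset(s) for s in ward_agglomerate(d1).node_leafsets()}
        s2 = {frozenset(s) for s in ward_agglomerate(d2).node_leafsets()}
        assert s1 == s2

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            ward_agglomerate(DistanceMatrix(("a",), np.zeros((1, 1))))


class TestBootstrap:
    def test_duplicate_samples_get_full_support(self, rng):
        base = rng.normal(size=(60, 1))
        x = np.concatenate(
            [base, base, base + 20, base - 20, rng.normal(30, 1, size=(60, 1))], axis=1
        )
        expr = pd.DataFrame(x, columns=["dup1", "dup2", "far1", "far2", "odd"])
        dend = bootstrap_support(expr, n_boot=200, seed=5)
        assert dend.support_for({"dup1", "dup2"}) == pytest.approx(100.0)

    def test_bp_range_and_determinism(self, rng):
        expr = pd.DataFrame(rng.normal(size=(40, 5)))
        expr.columns = [f"s{j}" for j in range(5)]
        a = bootstrap_support(expr, n_boot=100, seed=3)
        b = bootstrap_support(expr, n_boot=100, seed=3)
        assert ((a.bp >= 0) & (a.bp <= 100)).all()
        assert np.array_equal(a.bp, b.bp)

    def test_invalid_n_boot_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            bootstrap_support(expr, n_boot=0)


class TestStandardize:
    def test_hand_zscore(self):
        z = standardize_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert np.allclose(z.to_numpy(), [[-1.224744871, 0.0, 1.224744871]])

    def test_constant_row_maps_to_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z = standardize_rows(pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert (z.iloc[0] == 0).all()

    def test_rows_have_zero_mean(self, rng):
        z = standardize_rows(pd.DataFrame(rng.normal(2, 3, size=(20, 6))))
        assert np.abs(z.mean(axis=1)).max() < 1e-9


class TestKmeans:
    def test_k1_closed_form(self, rng):
        x = pd.DataFrame(rng.normal(size=(15, 4)))
        asg = kmeans_assign(x, k=1, seed=0)
        assert (asg.labels == 1).all()
        assert np.allclose(asg.centroids.iloc[0], x.mean(axis=0))

    def test_two_separated_blobs_recovered_exactly(self, rng):
        a = rng.normal(0, 0.2, size=(30, 3))
        b = rng.normal(10, 0.2, size=(25, 3))
        x = pd.DataFrame(np.concatenate([a, b]))
        asg = kmeans_assign(x, k=2, seed=1)
        labels = asg.labels.to_numpy()
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_best_of_restarts_by_inertia(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 4)))
        best = kmeans_assign(x, k=4, seed=2, n_init=25)
        single = kmeans_assign(x, k=4, seed=3, n_init=1)
        assert best.inertia <= single.inertia + 1e-9

    def test_invalid_inputs_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            kmeans_assign(x, k=0)
        with pytest.raises(ValueError):
            kmeans_assign(x, k=5)
        with pytest.raises(ValueError):
            kmeans_assign(pd.DataFrame(), k=1)


class TestTemplateLabelling:
    def _templates(self):
        return hm.default_cluster_templates()

    def test_exact_match_gives_identity(self):
        t = self._templates()
        centroids = t.copy()
        centroids.index = pd.RangeIndex(1, 5, name="cluster")
        mapping = label_clusters_by_template(centroids, t)
        assert mapping == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_permuted_centroids_recover_permutation(self):
        t = self._templates()
        perm = [3, 1, 4, 2]
        centroids = t.loc[perm].reset_index(drop=True)
        centroids.index = pd.RangeIndex(1, 5, name="cluster")
        mapping = label_clusters_by_template(centroids, t)
        assert [mapping[i] for i in range(1, 5)] == perm

    def test_noisy_centroids_still_match(self, rng):
        t = self._templates()
        for _ in range(20):
            noisy = t.to_numpy() + rng.normal(0, 0.1, size=t.shape)
            centroids = pd.DataFrame(
                noisy, index=pd.RangeIndex(1, 5, name="cluster"), columns=t.columns
            )
            mapping = label_clusters_by_template(centroids, t)
            assert sorted(mapping.values()) == [1, 2, 3, 4]
            assert mapping == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_dimension_mismatch_rejected(self):
        t = self._templates()
        with pytest.raises(ValueError):
            label_clusters_by_template(t.iloc[:3], t)


class TestGeneClusterRecovery:
    def test_kmeans_recovers_latent_clusters(self, default_experiment, default_de):
        """On the default preset, k-means at k=4 on z-scored condition-mean
        profiles of true-positive hypoxia-regulated genes recovers the latent
        clusters (adjusted Rand index >= 0.8)."""
        from sklearn.metrics import adjusted_rand_score
        from hifmimic.diffexp import compute_fpkm, log_expression

        _, counts, samples, truth = default_experiment
        hyp = default_de["hypoxia"]
        called = hyp.index[hyp["significant"]]
        tp = [g for g in called if truth.genes.at[g, "cluster"] != 0]
        logexpr = log_expression(compute_fpkm(counts)).values
        profiles = pd.DataFrame(
            {
                c: logexpr.loc[tp, samples.samples_for(c)].mean(axis=1)
                for c in samples.conditions
            }
        )
        asg = kmeans_assign(standardize_rows(profiles), k=4, seed=7)
        ari = adjusted_rand_score(truth.genes.loc[tp, "cluster"], asg.labels)
        assert ari >= 0.8
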