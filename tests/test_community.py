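"""Hill numbers, standardisations, ordination, clustering, IndVal, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from digesterkit.community import (
    ASVTable,
    aggregate_relative_abundance,
    bray_curtis,
    calinski_harabasz,
    choose_k,
    hellinger,
    hierarchical_linkage,
    hill_diversity,
    hill_evenness,
    indval,
    kmeans_cluster,
    nmds,
    one_way_anova,
)


class TestHillNumbers:
    def test_uniform_community(self):
        assert hill_diversity([10, 10, 10, 10], 1) == pytest.approx(4.0)
        assert hill_evenness([10, 10, 10, 10]) == pytest.approx(1.0)

    def test_two_taxon_hand_computation(self):
        # p = (0.75, 0.25): H = 0.562335, exp(H) = 1.75477
        d1 = hill_diversity([75, 25], 1)
        assert d1 == pytest.approx(1.75477, abs=1e-4)
        assert hill_evenness([75, 25]) == pytest.approx(1.75477 / 2.0, abs=1e-4)

    def test_single_taxon(self):
        assert hill_diversity([42], 1) == pytest.approx(1.0)
        assert hill_evenness([42]) == pytest.approx(1.0)

    def test_richness_bound(self, rng):
        for _ in range(20):
            row = rng.integers(0, 50, size=12)
            if row.sum() == 0:
                continue
            d1 = hill_diversity(row, 1)
            d0 = hill_diversity(row, 0)
            assert d1 <= d0 + 1e-9

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hill_diversity([0, 0, 0], 1)


class TestTransforms:
    def test_hellinger_row_example(self):
        out = hellinger([[1.0, 4.0]])
        np.testing.assert_allclose(out, [[0.44721, 0.89443]], atol=1e-5)

    def test_hellinger_unit_norms(self, rng):
        X = rng.integers(0, 30, (8, 15)) + 1
        norms = np.linalg.norm(hellinger(X), axis=1)
        np.testing.assert_allclose(norms, 1.0, rtol=1e-12)

    def test_bray_curtis_examples(self):
        D = bray_curtis([[1.0, 1.0], [0.0, 2.0], [1.0, 1.0]])
        assert D[0, 1] == pytest.approx(0.5)
        assert D[0, 2] == pytest.approx(0.0)
        assert bray_curtis([[1.0, 0.0], [0.0, 3.0]])[0, 1] == pytest.approx(1.0)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)

    def test_zero_sum_rows_rejected(self):
        with pytest.raises(ValueError):
            hellinger([[0.0, 0.0]])
        with pytest.raises(ValueError):
            bray_curtis([[0.0, 0.0], [1.0, 2.0]])


class TestNMDS:
    def test_equilateral_triangle_embeds_without_stress(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = nmds(D, restarts=4, seed=0)
        assert res.stress < 1e-4

    def test_recovers_planted_two_dimensional_configuration(self, rng):
        conf = rng.normal(0, 1, (12, 2))
        D = squareform(pdist(conf))
        res = nmds(D, restarts=8, seed=0)
        assert res.stress < 1e-3
        _, _, disparity = procrustes(conf, res.coordinates)
        assert disparity < 1e-3

    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.integers(1, 40, (9, 6)).astype(float)
        D = bray_curtis(X)
        a = nmds(D, restarts=5, seed=3)
        b = nmds(D, restarts=5, seed=3)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_coordinates_centred(self, rng):
        D = bray_curtis(rng.integers(1, 40, (7, 5)).astype(float))
        res = nmds(D, restarts=3, seed=1)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            nmds(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestKMeansAndCH:
    def test_two_separated_clouds(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (15, 2)), rng.normal(8, 0.2, (15, 2))])
        labels = kmeans_cluster(X, 2, seed=0)
        assert len(np.unique(labels[:15])) == 1
        assert len(np.unique(labels[15:])) == 1
        assert labels[0] != labels[-1]
        assert set(labels) == {1, 2}

    def test_duplicated_points_co_clustered(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 3))] * 2)
        labels = kmeans_cluster(X, 3, seed=0)
        np.testing.assert_array_equal(labels[:10], labels[10:])

    def test_seeded_reproducibility(self, rng):
        X = rng.normal(0, 1, (30, 4))
        np.testing.assert_array_equal(
            kmeans_cluster(X, 3, seed=5), kmeans_cluster(X, 3, seed=5)
        )

    def test_k_out_of_range(self, rng):
        X = rng.normal(0, 1, (5, 2))
        with pytest.raises(ValueError):
            kmeans_cluster(X, 5, seed=0)

    def test_ch_hand_computation(self):
        # clusters {0, 0.1} and {10, 10.1}: B = 100, W = 0.01,
        # CH = (100/1)/(0.01/2) = 20000
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([1, 1, 2, 2])
        assert calinski_harabasz(X, labels) == pytest.approx(20000.0, rel=1e-9)

    def test_ch_scale_invariance(self, rng):
        X = rng.normal(0, 1, (20, 3))
        labels = kmeans_cluster(X, 3, seed=0)
        assert calinski_harabasz(3.7 * X, labels) == pytest.approx(
            calinski_harabasz(X, labels), rel=1e-9
        )

    def test_ch_random_labels_near_one(self, rng):
        X = rng.normal(0, 1, (200, 2))
        values = [
            calinski_harabasz(X, rng.integers(1, 3, 200)) for _ in range(30)
        ]
        assert 0.3 < np.mean(values) < 3.0

    def test_ch_zero_within_scatter_is_infinite(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert np.isinf(calinski_harabasz(X, np.array([1, 1, 2, 2])))


class TestChooseK:
    def test_three_blobs_selects_three(self, rng):
        X = np.vstack([rng.normal(c, 0.3, (20, 2)) for c in ((0, 0), (5, 5), (0, 6))])
        res = choose_k(X, 6, seed=0)
        assert res.k == 3
        assert not res.weak_structure

    def test_single_blob_flags_weak_structure(self, rng):
        X = rng.normal(0, 1, (60, 2))
        res = choose_k(X, 6, seed=0)
        assert res.weak_structure
        assert res.k == 2

    def test_deterministic(self, rng):
        X = rng.normal(0, 1, (40, 3))
        a = choose_k(X, 5, seed=9)
        b = choose_k(X, 5, seed=9)
        assert a.k == b.k
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_dendrogram_side_artifact_shape(self, rng):
        X = rng.integers(1, 30, (10, 6)).astype(float)
        Z = hierarchical_linkage(bray_curtis(X))
        assert Z.shape == (9, 4)


class TestIndVal:
    def test_perfect_indicator(self, rng):
        n = 16
        labels = np.array([1] * 8 + [2] * 8)
        X = rng.poisson(5, (n, 4)) + 1
        X = np.column_stack([X, np.r_[np.full(8, 50), np.zeros(8)]])
        res = indval(pd.DataFrame(X), labels, n_perm=99, seed=0)
        row = res.summary.iloc[-1]
        assert row["indval"] == pytest.approx(100.0)
        assert row["cluster"] == 1
        assert row["p_value"] == pytest.approx(1.0 / 100.0)

    def test_equal_abundance_in_both_clusters_scores_fifty(self):
        # one taxon identical everywhere, another to avoid zero rows
        X = np.column_stack([np.full(10, 20.0), np.full(10, 5.0)])
        labels = np.array([1] * 5 + [2] * 5)
        res = indval(pd.DataFrame(X), labels, n_perm=49, seed=0)
        assert res.summary["indval"].iloc[0] == pytest.approx(50.0)

    def test_specificities_sum_to_one(self, rng):
        X = rng.poisson(4, (20, 30)) + (rng.random((20, 30)) < 0.6)
        X[:, 0] += 1  # keep all rows positive
        labels = rng.integers(1, 4, 20)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(1, 4, 20)
        res = indval(pd.DataFrame(X), labels, n_perm=9, seed=0)
        from digesterkit.community import _indval_components

        P = X / X.sum(axis=1, keepdims=True)
        _, A, _ = _indval_components(P, labels, np.unique(labels))
        np.testing.assert_allclose(A.sum(axis=0), 1.0, rtol=1e-9)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(42)
        X = rng.poisson(5, (24, 120)) + 1
        labels = np.array([1] * 12 + [2] * 12)
        res = indval(pd.DataFrame(X), labels, n_perm=199, seed=1)
        ks = stats.kstest(res.summary["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_requires_two_clusters(self):
        with pytest.raises(ValueError):
            indval(pd.DataFrame(np.ones((4, 3))), np.array([1, 1, 1, 1]))


def _asv_table():
    counts = pd.DataFrame(
        {
            "asv1": [50, 40, 30],
            "asv2": [50, 55, 60],
            "asv3": [2, 3, 1],
            "asv4": [1, 0, 2],
        },
        index=["s1", "s2", "s3"],
    )
    taxonomy = pd.Series(
        {
            "asv1": "Bacteria;F1;C1;O1;Fam1;GenA",
            "asv2": "Bacteria;F1;C1;O1;Fam1;GenA",
            "asv3": "Bacteria;F2;C2;O2;Fam2;GenB",
            "asv4": "Bacteria;F2;C2;O2;Fam2;GenC",
        }
    )
    meta = pd.DataFrame(
        {"reactor": ["R1", "R1", "R2"], "day": [10, 20, 10]},
        index=["s1", "s2", "s3"],
    )
    return ASVTable(counts=counts, taxonomy=taxonomy, metadata=meta)


class TestASVTable:
    def test_rank_aggregation_sums_counts(self):
        agg = _asv_table().aggregate_by_rank("genus")
        assert agg.loc["s1", "GenA"] == 100
        assert set(agg.columns) == {"GenA", "GenB", "GenC"}

    def test_relative_abundance_pools_rare_groups(self):
        rel = aggregate_relative_abundance(_asv_table(), rank="genus", floor=0.05)
        assert rel.shape[1] == 2  # GenA + pooled rare
        np.testing.assert_allclose(rel.sum(axis=1), 1.0)
        pooled = [c for c in rel.columns if "abundance" in c]
        assert pooled

    def test_single_genus_table(self):
        t = _asv_table()
        counts = t.counts[["asv1", "asv2"]]
        table = ASVTable(counts=counts, taxonomy=t.taxonomy, metadata=t.metadata)
        rel = aggregate_relative_abundance(table, rank="genus")
        np.testing.assert_allclose(rel["GenA"], 1.0)

    def test_tsv_round_trip(self, tmp_path):
        t = _asv_table()
        t.to_tsv(tmp_path / "counts.tsv", tmp_path / "meta.tsv")
        back = ASVTable.from_tsv(tmp_path / "counts.tsv", tmp_path / "meta.tsv")
        pd.testing.assert_frame_equal(back.counts, t.counts)
        assert list(back.metadata["reactor"]) == ["R1", "R1", "R2"]

    def test_duplicate_sample_ids_rejected(self):
        t = _asv_table()
        counts = pd.concat([t.counts, t.counts.iloc[[0]]])
        meta = pd.concat([t.metadata, t.metadata.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            ASVTable(counts=counts, taxonomy=t.taxonomy, metadata=meta)


class TestAnova:
    def test_hand_computed_f_statistic(self):
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert res.F == pytest.approx(13.5)
        assert 0 < res.p_value < 0.05

    def test_identical_groups_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.F == pytest.approx(0.0)

    def test_shift_invariance(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        res1 = one_way_anova([a, b])
        res2 = one_way_anova([a + 100.0, b + 100.0])
        assert res1.F == pytest.approx(res2.F, rel=1e-9)

    def test_degenerate_case_flagged(self):
        res = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert res.degenerate
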