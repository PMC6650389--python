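"""k-means + silhouette k selection, PCA embedding, Fisher enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from morphoscreen.clustering import kmeans, pca_embed, select_k_by_silhouette
from morphoscreen.enrichment import fisher_enrichment, two_tailed_fisher


def fisher_enumeration_oracle(a, b, c, d):
    """Two-tailed Fisher p by explicit enumeration over the hypergeometric
    support: sum of probabilities of all tables (same margins) whose
    probability does not exceed the observed table's."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())


def _blobs(rng, k=3, n=40, sep=8.0, p=6):
    centers = rng.normal(size=(k, p)) * sep
    X = np.vstack([centers[i] + rng.normal(size=(n, p)) for i in range(k)])
    labels = np.repeat(np.arange(k), n)
    return X, labels


class TestKMeans:
    def test_two_points_two_clusters(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        assign, inertia = kmeans(X, 2, rng=0)
        assert sorted(assign) == [1, 2]
        assert inertia == 0.0

    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X, truth = _blobs(rng)
        assign, _ = kmeans(X, 3, rng=1)
        assert adjusted_rand_score(truth, assign) == 1.0

    def test_duplicate_rows_same_assignment(self):
        rng = np.random.default_rng(1)
        X, _ = _blobs(rng, k=2)
        X2 = np.vstack([X, X])
        assign, _ = kmeans(X2, 2, rng=2)
        assert np.array_equal(assign[: len(X)], assign[len(X) :])

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans(np.zeros((3, 2)), 5, rng=0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(2)
        X, _ = _blobs(rng)
        a1, i1 = kmeans(X, 3, rng=7)
        a2, i2 = kmeans(X, 3, rng=7)
        assert np.array_equal(a1, a2) and i1 == i2


class TestSelectK:
    def test_planted_three_clusters_found(self):
        rng = np.random.default_rng(3)
        X, truth = _blobs(rng, k=3)
        res = select_k_by_silhouette(X, range(2, 9), rng=0)
        assert res.k == 3
        assert adjusted_rand_score(truth, res.assignment) == 1.0
        assert np.all((res.silhouette >= -1) & (res.silhouette <= 1))

    def test_single_blob_reports_no_structure(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 5))
        res = select_k_by_silhouette(X, range(2, 6), rng=0)
        # an isotropic blob: either no structure or a very weak best silhouette
        assert res.k is None or max(res.mean_silhouette_by_k.values()) < 0.3

    def test_two_tight_far_clusters_silhouette_near_one(self):
        X = np.vstack([np.zeros((10, 3)), np.full((10, 3), 100.0)])
        X += np.random.default_rng(5).normal(scale=1e-3, size=X.shape)
        res = select_k_by_silhouette(X, range(2, 4), rng=0)
        assert res.k == 2
        assert res.mean_silhouette_by_k[2] > 0.99

    def test_recovery_rate_over_seeded_replicates(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X, _ = _blobs(rng, k=3, n=30, sep=6.0)
            res = select_k_by_silhouette(X, range(2, 7), rng=seed)
            hits += res.k == 3
        assert hits >= 29


class TestPCAEmbed:
    def test_line_collapses_to_first_axis(self):
        t = np.linspace(0, 1, 50)
        X = np.outer(t, [1.0, 2.0, 3.0]) + 1e-9 * np.random.default_rng(0).normal(size=(50, 3))
        emb = pca_embed(X)
        assert np.abs(emb[:, 1]).max() < 1e-3 * np.abs(emb[:, 0]).max()

    def test_projection_contracts_distances(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 10))
        emb = pca_embed(X)
        mean = X.mean(0)
        sd = X.std(0, ddof=1)
        Z = (X - mean) / sd
        for i in range(0, 30, 7):
            for j in range(1, 30, 9):
                d_full = np.linalg.norm(Z[i] - Z[j])
                d_emb = np.linalg.norm(emb[i] - emb[j])
                assert d_emb <= d_full + 1e-9

    def test_wildtype_near_origin_when_mutants_extreme(self):
        rng = np.random.default_rng(7)
        wt = rng.normal(size=(50, 6)) * 0.3
        mut = rng.normal(size=(20, 6)) * 0.3 + rng.choice([-5, 5], size=(20, 6))
        emb = pca_embed(np.vstack([wt, mut]))
        assert np.linalg.norm(emb[:50], axis=1).mean() < np.linalg.norm(emb[50:], axis=1).mean()


class TestFisher:
    def test_example_table_matches_enumeration(self):
        p = two_tailed_fisher([[5, 1], [10, 84]])
        assert abs(p - fisher_enumeration_oracle(5, 1, 10, 84)) < 1e-12

    def test_extreme_split_closed_form(self):
        n, m = 6, 5
        p = two_tailed_fisher([[0, n], [m, 0]])
        total = n + m
        # the observed table is the unique most extreme one in its tail
        expected = fisher_enumeration_oracle(0, n, m, 0)
        assert abs(p - expected) < 1e-12
        assert p == pytest.approx(expected)

    def test_category_in_every_strain_gives_p_one(self):
        members = {f"s{i}": 1 + i % 2 for i in range(10)}
        cats = {f"s{i}": "M" for i in range(10)}
        out = fisher_enrichment(members, cats)
        assert (out["p_value"] == 1.0).all()

    def test_margins_up_to_twelve_match_enumeration(self):
        for a in range(0, 6):
            for b in range(0, 6):
                for c in range(0, 6):
                    for d in range(0, 6):
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        p = two_tailed_fisher([[a, b], [c, d]])
                        o = fisher_enumeration_oracle(a, b, c, d)
                        assert abs(p - o) < 1e-12, (a, b, c, d)

    def test_planted_enrichment_detected(self):
        members = {f"s{i}": (1 if i < 20 else 2) for i in range(60)}
        cats = {f"s{i}": ("L" if i < 15 else "J") for i in range(60)}
        out = fisher_enrichment(members, cats)
        row = out[(out.cluster == 1) & (out.category == "L")].iloc[0]
        assert row.significant and row.p_value < 1e-6
        assert row.in_cluster_with == 15

    def test_table_margins_consistent(self):
        members = {f"s{i}": 1 + (i % 3) for i in range(30)}
        rng = np.random.default_rng(8)
        cats = {f"s{i}": "".join(rng.choice(list("JKLM"), size=2, replace=False)) for i in range(30)}
        out = fisher_enrichment(members, cats)
        tot = (
            out.in_cluster_with + out.in_cluster_without + out.out_cluster_with + out.out_cluster_without
        )
        assert (tot == 30).all()
        assert ((out.p_value > 0) & (out.p_value <= 1)).all()
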