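"""Artificial-doublet simulation, kNN scores and the consensus rule."""

import numpy as np
import pandas as pd
import pytest

from hybridsc.doublets import (
    DoubletConfig,
    adjudicate_clusters,
    doublet_scores,
    score_from_embedding,
    simulate_artificial_doublets,
)
from hybridsc.hybrid_calls import HybridCall

from conftest import make_counts


@pytest.fixture()
def small_counts():
    rng = np.random.default_rng(0)
    return make_counts(rng.poisson(2.0, size=(40, 300)) + 1)


class TestSimulation:
    def test_artificial_columns_are_pair_sums_and_seeded(self, small_counts):
        cfg = DoubletConfig(seed=3)
        art1 = simulate_artificial_doublets(small_counts, cfg)
        art2 = simulate_artificial_doublets(small_counts, cfg)
        assert (art1.values != art2.values).nnz == 0
        X = small_counts.values.toarray()
        A = art1.values.toarray()
        # every artificial column must be expressible as a sum of two
        # distinct observed columns (verify via total-count conservation
        # and membership for a few columns)
        col_sums = X.sum(axis=0)
        for j in range(5):
            total = A[:, j].sum()
            matches = [
                (a, b)
                for a in range(X.shape[1])
                for b in range(a + 1, X.shape[1])
                if col_sums[a] + col_sums[b] == total
                and np.array_equal(X[:, a] + X[:, b], A[:, j])
            ]
            assert matches

    def test_pann_count_convention(self, small_counts):
        """pN = 0.25 makes artificial cells 25% of the merged set:
        round(0.25/0.75 x 300) = 100."""
        art = simulate_artificial_doublets(small_counts, DoubletConfig(pN=0.25))
        assert art.n_cells == 100

    def test_explicit_n_art(self, small_counts):
        art = simulate_artificial_doublets(small_counts, DoubletConfig(), n_art=37)
        assert art.n_cells == 37

    def test_invalid_pn_rejected(self):
        with pytest.raises(ValueError):
            DoubletConfig(pN=1.0).validate()


class TestScores:
    def test_merged_neighborhood_size(self):
        """pK = 0.09 on a merged set of 400 gives K = 36 neighbors."""
        assert round(0.09 * 400) == 36
        rng = np.random.default_rng(1)
        counts = make_counts(rng.poisson(2.0, size=(30, 300)) + 1)
        cfg = DoubletConfig(pN=0.25, pK=0.09, seed=0)
        art = simulate_artificial_doublets(counts, cfg)
        assert counts.n_cells + art.n_cells == 400

    def test_pann_is_one_when_surrounded_by_artificial(self):
        rng = np.random.default_rng(0)
        n_obs, n_art = 50, 150
        coords = np.vstack(
            [
                rng.normal(0, 0.1, (1, 2)),          # observed cell inside the ball
                rng.normal(100, 0.1, (n_obs - 1, 2)),  # far-away observed cells
                rng.normal(0, 0.1, (n_art, 2)),       # artificial ball at origin
            ]
        )
        cfg = DoubletConfig(pK=0.09, k_sim=20)
        pann = score_from_embedding(coords, n_obs, n_art, cfg, "pann")
        assert pann[0] == 1.0
        assert 0.0 <= pann.min() and pann.max() <= 1.0

    def test_knn_fraction_zero_without_artificial_neighbors(self):
        rng = np.random.default_rng(0)
        coords = np.vstack(
            [rng.normal(0, 0.1, (60, 2)), rng.normal(100, 0.1, (60, 2))]
        )
        cfg = DoubletConfig(k_sim=10)
        s = score_from_embedding(coords, 60, 60, cfg, "knn_fraction")
        np.testing.assert_allclose(s, 0.0)

    def test_density_ratio_elevated_inside_artificial_ball(self):
        rng = np.random.default_rng(0)
        n_obs, n_art = 100, 100
        coords = np.vstack(
            [
                np.zeros((1, 2)),                      # planted at ball centroid
                rng.normal(50, 1.0, (n_obs - 1, 2)),
                rng.normal(0, 0.1, (n_art, 2)),
            ]
        )
        cfg = DoubletConfig(k_sim=20)
        s = score_from_embedding(coords, n_obs, n_art, cfg, "density_ratio")
        assert s[0] > 1.0
        assert (s >= 0).all() and np.isfinite(s).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            score_from_embedding(np.zeros((4, 2)), 2, 2, DoubletConfig(), "votes")

    def test_scores_bounded_and_deterministic(self, small_counts):
        cfg = DoubletConfig(seed=5, k_sim=20)
        t1 = doublet_scores(small_counts, cfg)
        t2 = doublet_scores(small_counts, cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert t1["pann"].between(0, 1).all()
        assert t1["knn_fraction"].between(0, 1).all()
        assert (t1["density_ratio"] >= 0).all()


def make_score_table(per_cluster, n=30):
    rows = []
    clusters = []
    rng = np.random.default_rng(0)
    for cl, level in per_cluster.items():
        for _ in range(n):
            base = rng.normal(level, 0.01)
            rows.append({"barcode": f"{cl}-{_}", "pann": base, "knn_fraction": base, "density_ratio": base})
            clusters.append(cl)
    return pd.DataFrame(rows), np.array(clusters)


class TestAdjudication:
    def test_middling_cluster_not_flagged(self):
        table, clusters = make_score_table({i: 0.1 * i for i in range(10)})
        adj, _ = adjudicate_clusters(table, clusters)
        by = {a.cluster: a for a in adj}
        assert not by[5].flagged_doublet          # 50th percentile
        assert by[9].flagged_doublet              # top of all three methods

    def test_identical_clusters_share_low_rank(self):
        table, clusters = make_score_table({0: 0.5, 1: 0.5})
        table[["pann", "knn_fraction", "density_ratio"]] = 0.5
        adj, _ = adjudicate_clusters(table, clusters)
        assert not any(a.flagged_doublet for a in adj)

    def test_single_cluster_returns_unflagged(self):
        table, clusters = make_score_table({0: 0.9})
        adj, _ = adjudicate_clusters(table, clusters)
        assert len(adj) == 1 and not adj[0].flagged_doublet

    def test_flagged_cluster_demotes_hybrid_call(self):
        table, clusters = make_score_table({i: 0.1 * i for i in range(10)})
        calls = [HybridCall(cluster=9, is_hybrid=True), HybridCall(cluster=5, is_hybrid=True)]
        _, updated = adjudicate_clusters(table, clusters, calls)
        by = {c.cluster: c for c in updated}
        assert not by[9].is_hybrid and by[9].demotion_reason
        assert by[5].is_hybrid and by[5].demotion_reason is None


class TestOnSyntheticTruth:
    def test_spiked_doublets_score_above_singlets(self, default_result):
        """Median spiked-doublet score exceeds the 90th percentile of
        singlet scores for at least two of the three methods."""
        result, truth = default_result
        table = result.doublet_table.set_index("barcode")
        pop = truth.set_index("barcode")["population"].reindex(table.index)
        n_sep = 0
        for m in ("pann", "knn_fraction", "density_ratio"):
            dbl = table.loc[pop == "doublet", m]
            sng = table.loc[pop != "doublet", m]
            n_sep += dbl.median() > sng.quantile(0.9)
        assert n_sep >= 2

    def test_hybrid_cluster_not_flagged_but_doublet_cluster_is(self, default_result):
        result, truth = default_result
        labels = result.cluster_labels
        ct = pd.crosstab(truth["population"].to_numpy(), labels)
        hybrid_cluster = ct.loc["hybrid"].idxmax()
        frac = ct / ct.sum(0)
        doublet_clusters = [c for c in ct.columns if frac.loc["doublet", c] > 0.5]
        flagged = {a.cluster for a in result.adjudications if a.flagged_doublet}
        assert hybrid_cluster not in flagged
        assert doublet_clusters and set(doublet_clusters) <= flagged
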